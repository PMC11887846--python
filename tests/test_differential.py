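import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pseudomics.covariates import DesignMatrix
from pseudomics.differential import (
    Contrast,
    DifferentialConfig,
    bh_adjust,
    check_residual_normality,
    estimate_dispersion,
    fit_lm_wald,
    fit_nb_glm_wald,
    run_differential,
)
from pseudomics.synthetic import TruthSpec, generate_cohort, generate_expression_counts

from conftest import make_assay


def _design(X: np.ndarray, voi_col: int = 1) -> DesignMatrix:
    cols = ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
    cols[voi_col] = "group"
    return DesignMatrix(matrix=pd.DataFrame(X, columns=cols), variable_of_interest="group")


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Definition-level BH: fdr_i = min over j with p_(j) >= p_i of p_(j)*m/j."""
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        out[idx] = min(1.0, min(candidates))
    return out


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        # m=2 for the valid entries
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.5])

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(100))
        fdr = bh_adjust(p)
        assert (np.diff(fdr) >= -1e-12).all()


class TestLinearModel:
    def test_response_equal_to_indicator_recovers_unit_coefficient(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        y = X[:, 1] + 1e-8 * rng.normal(size=8)  # group signal, negligible noise
        scores = pd.DataFrame((2.0**y - 1.0)[None, :], index=["g"])
        res, _ = fit_lm_wald(scores, _design(X))
        assert res["log2FC"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert res["p_value"].iloc[0] < 1e-10

    def test_matches_normal_equations_oracle(self):
        """Coefficient and SE equal the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            p = int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                                 rng.normal(size=(n, p - 2))]) if p > 2 else \
                np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            y = rng.normal(size=n)
            scores = pd.DataFrame((2.0**y - 1.0)[None, :].clip(min=0))
            ylog = np.log2(scores.to_numpy() + 1).ravel()
            res, _ = fit_lm_wald(scores, _design(X))
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ ylog
            resid = ylog - X @ beta
            sigma2 = resid @ resid / (n - X.shape[1])
            se = np.sqrt(sigma2 * XtX_inv[1, 1])
            assert res["log2FC"].iloc[0] == pytest.approx(beta[1], abs=1e-10)
            assert res["SE"].iloc[0] == pytest.approx(se, abs=1e-10)

    def test_gaussian_null_type_i_error(self):
        rng = np.random.default_rng(3)
        n, G = 40, 2000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                             rng.normal(size=(n, 3))])
        Y = rng.normal(size=(G, n))
        res, _ = fit_lm_wald(pd.DataFrame(Y), _design(X), already_log=True)
        frac = (res["p_value"] <= 0.05).mean()
        assert 0.040 <= frac <= 0.060

    def test_too_few_samples_rejected(self):
        X = np.column_stack([np.ones(3), [0, 1, 0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="more samples"):
            fit_lm_wald(pd.DataFrame(np.ones((2, 3))), _design(X))


class TestNBGLM:
    def test_poisson_limit_matches_statsmodels_oracle(self):
        """At the dispersion floor the NB IRLS equals a Poisson GLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 30
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                             rng.normal(size=n)])
        sf = np.exp(rng.uniform(-0.3, 0.3, n))
        mu = sf * np.exp(0.5 + 0.8 * X[:, 1] + 0.2 * X[:, 2])
        counts = rng.poisson(mu, size=(25, n))
        res = fit_nb_glm_wald(pd.DataFrame(counts), _design(X), sf,
                              dispersion=np.full(25, 1e-8))
        for i in range(25):
            fit = sm.GLM(counts[i], X, family=sm.families.Poisson(),
                         offset=np.log(sf)).fit()
            assert res["log2FC"].iloc[i] * np.log(2) == pytest.approx(fit.params[1], abs=1e-3)
            assert res["SE"].iloc[i] * np.log(2) == pytest.approx(fit.bse[1], abs=1e-3)

    def test_two_group_poisson_fit_equals_log_ratio_of_normalized_sums(self):
        """With intercept+group at the dispersion floor, the MLE is the
        offset-weighted group mean ratio (sum y / sum sf per group)."""
        rng = np.random.default_rng(5)
        n = 40
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        sf = np.exp(rng.uniform(-0.5, 0.5, n))
        counts = rng.negative_binomial(10, 10 / (10 + 50 * sf))[None, :]
        res = fit_nb_glm_wald(pd.DataFrame(counts), _design(X), sf,
                              dispersion=np.array([1e-8]))
        hi, lo = slice(n // 2, None), slice(None, n // 2)
        expected = np.log2((counts[0, hi].sum() / sf[hi].sum())
                           / (counts[0, lo].sum() / sf[lo].sum()))
        assert res["log2FC"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(6)
        n, G = 40, 200
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        mu = 100.0 * 2.0 ** X[:, 1]
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu), size=(G, n))
        res = fit_nb_glm_wald(pd.DataFrame(counts), _design(X), np.ones(n))
        assert abs(res["log2FC"].mean() - 1.0) <= 0.1

    def test_all_zero_gene_reported_na(self):
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 20)])
        res = fit_nb_glm_wald(pd.DataFrame(counts), _design(X), np.ones(6))
        assert np.isnan(res["p_value"].iloc[0])
        assert np.isfinite(res["p_value"].iloc[1])

    def test_dispersion_estimate_floor_and_moments(self):
        rng = np.random.default_rng(7)
        # dispersion 0.2, large n: MoM should land near the truth
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + 100.0), size=(5, 4000))
        alpha = estimate_dispersion(counts, np.ones(4000))
        np.testing.assert_allclose(alpha, 0.2, rtol=0.15)
        under = rng.poisson(3.0, size=(5, 50))
        assert (estimate_dispersion(under, np.ones(50)) >= 1e-8).all()


class TestResidualNormality:
    def test_gaussian_residuals_rejected_at_alpha(self):
        rng = np.random.default_rng(8)
        resid = pd.DataFrame(rng.normal(size=(1000, 30)))
        out = check_residual_normality(resid)
        assert abs(out.attrs["rejected_fraction"] - 0.05) < 0.025

    def test_exponential_residuals_mostly_rejected(self):
        rng = np.random.default_rng(9)
        resid = pd.DataFrame(rng.exponential(size=(200, 30)))
        out = check_residual_normality(resid)
        assert out.attrs["rejected_fraction"] > 0.5

    def test_constant_residuals_na(self):
        with pytest.warns(UserWarning, match="no usable genes"):
            out = check_residual_normality(pd.DataFrame(np.ones((3, 10))))
        assert np.isnan(out["p_value"]).all()


class TestRunDifferential:
    def test_deterministic_given_inputs(self, cohort40):
        assays, _ = generate_expression_counts(cohort40, ["ct"], 100, TruthSpec(), seed=1)
        a = run_differential(assays["ct"], cohort40, Contrast(kind="diagnosis"))
        b = run_differential(assays["ct"], cohort40, Contrast(kind="diagnosis"))
        pd.testing.assert_frame_equal(a, b)

    def test_result_table_contract(self, cohort40):
        assays, _ = generate_expression_counts(cohort40, ["ct"], 100, TruthSpec(), seed=2)
        res = run_differential(assays["ct"], cohort40, Contrast(kind="diagnosis"))
        ok = res.dropna(subset=["p_value"])
        assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()
        assert ((ok["fdr"] >= 0) & (ok["fdr"] <= 1)).all()
        assert (ok["SE"] > 0).all()
        srt = ok.sort_values("p_value")
        assert (np.diff(srt["fdr"]) >= -1e-12).all()  # fdr monotone in p
        assert res["contrast"].eq("diagnosis").all()
        assert res["n_samples_used"].nunique() == 1

    def test_too_few_samples_skips_cell_type(self):
        cohort = generate_cohort(5, seed=3)
        assays, _ = generate_expression_counts(cohort, ["ct"], 50, TruthSpec(), seed=4)
        with pytest.warns(UserWarning, match="skipping"):
            out = run_differential(assays["ct"], cohort, Contrast(kind="diagnosis"),
                                   DifferentialConfig(min_samples=6))
        assert out is None

    def test_risk_contrast_uses_matched_donors_only(self, cohort_with_prs):
        cohort, prs = cohort_with_prs
        from pseudomics.risk import define_risk_groups

        rg = define_risk_groups(cohort, prs, "schizophrenia")
        assays, _ = generate_expression_counts(cohort, ["ct"], 80, TruthSpec(), seed=5)
        contrast = Contrast(kind="risk", trait="schizophrenia",
                            assignment=rg.assignment_frame())
        res = run_differential(assays["ct"], cohort, contrast)
        assert res["contrast"].eq("risk:schizophrenia").all()
        assert res["n_samples_used"].iloc[0] <= len(rg.assignment_frame())
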