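"""Per-gene Wald tests on pseudobulk data.

Differential expression uses a negative-binomial GLM with a log link and
library-size offsets, gene-wise method-of-moments dispersion (no shrinkage),
and a Wald test of the group coefficient. Differential accessibility fits
ordinary least squares to log2(cell-count-normalized gene score + 1) with a
t-referenced Wald statistic. Both share the covariate model (including the
hidden-noise PC) and Benjamini-Hochberg FDR control; genes at FDR <= 0.1
are reported as significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PseudobulkAssay
from .covariates import (
    DesignMatrix,
    build_design,
    compute_noise_pc,
    impute_rin,
    remove_outliers_iterative,
    transform_counts,
)
from .pseudobulk import filter_features, normalize_gene_scores

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialConfig",
    "Contrast",
    "bh_adjust",
    "estimate_dispersion",
    "fit_nb_glm_wald",
    "fit_lm_wald",
    "check_residual_normality",
    "run_differential",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

DE_COVARIATES = ("sex", "age", "brain_pH", "rin", "pmi", "lib_batch")
DA_COVARIATES = ("sex", "age", "brain_pH", "pmi", "lib_batch")  # RIN excluded for ATAC


@dataclass(frozen=True)
class DifferentialConfig:
    """Thresholds of the differential-testing pipeline (study defaults)."""

    min_count: float = 10.0  # counts filter: >= 10 in 75% of samples
    min_count_fraction: float = 0.75
    min_score: float = 0.1  # gene-score filter: > 0.1 in 75% of samples
    min_score_fraction: float = 0.75
    fdr_threshold: float = 0.1
    outlier_sd: float = 3.0
    min_samples: int = 6
    pseudocount: float = 1.0
    use_noise_pc: bool = True


@dataclass(frozen=True)
class Contrast:
    """What is being compared: diagnosis (case vs control) or a risk trait.

    For ``kind="risk"`` an assignment table (donor_id, group in
    {high, low}) from the matching stage restricts and labels the donors,
    and lib_batch is dropped from the design.
    """

    kind: str  # "diagnosis" | "risk"
    trait: str | None = None
    assignment: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("diagnosis", "risk"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.kind == "risk" and self.assignment is None:
            raise ValueError("risk contrast needs a matched-group assignment")

    @property
    def label(self) -> str:
        return "diagnosis" if self.kind == "diagnosis" else f"risk:{self.trait}"


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs pass through and are not counted."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if not ok.any():
        return out
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    out[ok] = result
    return out


def estimate_dispersion(
    counts: np.ndarray, size_factors: np.ndarray, floor: float = DISPERSION_FLOOR
) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments on normalized counts."""
    q = counts / size_factors[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(alpha, floor)


def fit_nb_glm_wald(
    counts: pd.DataFrame,
    design: DesignMatrix,
    size_factors: np.ndarray | pd.Series,
    dispersion: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """NB GLM Wald test of the variable of interest, one row per gene.

    The model is ``log mu = log(size_factor) + X beta`` with fixed gene-wise
    dispersion; coefficients come from iteratively reweighted least squares
    (relative tolerance ``tol``, at most ``max_iter`` iterations, vectorized
    over genes), the Wald SE from the expected information matrix, and
    log2FC = coefficient / ln 2. All-zero genes and non-converged fits are
    reported with NA statistics.
    """
    Y = counts.to_numpy(dtype=float)
    X = design.array()
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    sf = np.asarray(size_factors, dtype=float)
    offset = np.log(sf)
    G = Y.shape[0]
    if dispersion is None:
        dispersion = estimate_dispersion(Y, sf)
    alpha = np.asarray(dispersion, dtype=float)

    nonzero = Y.sum(axis=1) > 0
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    active = nonzero.copy()
    mu0 = np.maximum(Y, 0.5)
    eta = np.log(mu0) - offset[None, :]  # linear predictor without offset
    # warm start: project the log-scale start onto the design column space
    beta[:] = np.linalg.lstsq(X, eta.T, rcond=None)[0].T
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta_a = beta[idx] @ X.T
        mu = np.exp(np.clip(eta_a + offset[None, :], -30.0, 30.0))
        W = mu / (1.0 + alpha[idx, None] * mu)
        z = eta_a + (Y[idx] - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True)
        XtWz = np.einsum("gn,gn,np->gp", W, z, X, optimize=True)
        XtWX += np.eye(p)[None, :, :] * 1e-10  # ridge against degenerate weights
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
            break
        delta = np.abs(new_beta - beta[idx]).max(axis=1)
        scale = np.maximum(np.abs(new_beta).max(axis=1), 1.0)
        beta[idx] = new_beta
        done = delta / scale < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # Wald SE at the final fit
    eta_f = beta @ X.T
    mu = np.exp(np.clip(eta_f + offset[None, :], -30.0, 30.0))
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True)
    XtWX += np.eye(p)[None, :, :] * 1e-10
    cov = np.linalg.inv(XtWX)
    j = design.voi_index()
    se_ln = np.sqrt(np.maximum(cov[:, j, j], 0.0))
    coef_ln = beta[:, j]
    wald = np.where(se_ln > 0, coef_ln / se_ln, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    ok = nonzero & converged & (se_ln > 0)
    n_failed = int((nonzero & ~converged).sum())
    if n_failed:
        logger.info("%d NB fits did not converge; reported as NA", n_failed)
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2FC": np.where(ok, coef_ln / LN2, np.nan),
            "SE": np.where(ok, se_ln / LN2, np.nan),
            "wald_statistic": np.where(ok, wald, np.nan),
            "p_value": np.where(ok, pvals, np.nan),
            "converged": converged,
            "dispersion": alpha,
        }
    )
    return out


def fit_lm_wald(
    scores: pd.DataFrame,
    design: DesignMatrix,
    pseudocount: float = 1.0,
    already_log: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS Wald test on log2(normalized gene score + pseudocount).

    Returns ``(results, residuals)``: the per-gene coefficient of the
    variable of interest (which is the log2FC), its SE, the t-referenced
    Wald statistic (df = n - p) and p-value, plus the residual matrix for
    normality diagnostics.
    """
    X = design.array()
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns for OLS")
    raw = scores.to_numpy(dtype=float)
    Y = raw if already_log else np.log2(raw + pseudocount)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # p x G
    resid = Y.T - X @ beta  # n x G
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / (n - p)
    j = design.voi_index()
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    coef = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    results = pd.DataFrame(
        {
            "gene_id": scores.index,
            "log2FC": coef,
            "SE": se,
            "wald_statistic": tstat,
            "p_value": np.where(se > 0, pvals, np.nan),
        }
    )
    residuals = pd.DataFrame(resid.T, index=scores.index, columns=scores.columns)
    return results, residuals


def check_residual_normality(residuals: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk per gene on model residuals; advisory only.

    The returned frame carries ``rejected_fraction`` in ``attrs`` — the
    share of genes whose residuals deviate from normality at ``alpha``.
    """
    R = residuals.to_numpy(dtype=float)
    stats_w = np.full(R.shape[0], np.nan)
    pvals = np.full(R.shape[0], np.nan)
    for i, row in enumerate(R):
        if len(row) < 3 or np.ptp(row) == 0:
            continue
        w, pv = stats.shapiro(row)
        stats_w[i], pvals[i] = w, pv
    out = pd.DataFrame(
        {"gene_id": residuals.index, "shapiro_w": stats_w, "p_value": pvals}
    )
    ok = ~np.isnan(pvals)
    out.attrs["rejected_fraction"] = float((pvals[ok] <= alpha).mean()) if ok.any() else np.nan
    if not ok.any():
        warnings.warn("residual normality check produced no usable genes")
    return out


def _contrast_sample_table(
    pb: PseudobulkAssay, cohort: pd.DataFrame, contrast: Contrast
) -> tuple[pd.DataFrame, str]:
    """Per-sample covariate table with the 0/1 variable of interest."""
    meta = pb.sample_meta
    cohort_idx = cohort.set_index("donor_id")
    table = cohort_idx.loc[meta["donor_id"]].reset_index()
    table.index = meta.index
    if contrast.kind == "diagnosis":
        voi = "Disease_Status"
        table[voi] = (table["disease_status"] == "case").astype(float)
    else:
        assign = contrast.assignment.set_index("donor_id")["group"]
        table["group"] = assign.reindex(table["donor_id"]).to_numpy()
        table = table[table["group"].isin(["high", "low"])]
        voi = "Genetic_Risk"
        table[voi] = (table["group"] == "high").astype(float)
    return table, voi


def run_differential(
    pb: PseudobulkAssay,
    cohort: pd.DataFrame,
    contrast: Contrast,
    config: DifferentialConfig | None = None,
) -> pd.DataFrame | None:
    """Full per-cell-type differential pipeline on one pseudobulk assay.

    Order: feature filter -> (DE: size factors / DA: cell-count
    normalization and log transform) -> iterative PC1 outlier removal ->
    RIN median imputation -> design with hidden-noise PC -> per-gene Wald
    fit -> BH adjustment. Returns a tidy table, or ``None`` when fewer than
    ``config.min_samples`` samples survive outlier removal.
    """
    cfg = config or DifferentialConfig()
    is_rna = pb.modality == "rna_counts"

    sample_table, voi = _contrast_sample_table(pb, cohort, contrast)
    pb = pb.subset_samples(list(sample_table.index))

    if is_rna:
        pb = filter_features(pb, cfg.min_count, cfg.min_count_fraction)
    else:
        if not pb.normalized:
            pb = normalize_gene_scores(pb)
        pb = filter_features(pb, cfg.min_score, cfg.min_score_fraction)
    if pb.n_features == 0:
        warnings.warn("no features survive filtering")
        return None

    if is_rna:
        transformed, _ = transform_counts(pb.values)
    else:
        transformed = np.log2(pb.values + cfg.pseudocount)

    kept, removal_log = remove_outliers_iterative(transformed, cfg.outlier_sd)
    if removal_log:
        logger.info("outlier removal dropped %d samples", pb.n_samples - len(kept))
    if len(kept) < cfg.min_samples:
        warnings.warn(
            f"only {len(kept)} samples remain after outlier removal; skipping "
            f"cell type {pb.sample_meta['cell_type'].iloc[0]!r}"
        )
        return None
    pb = pb.subset_samples(kept)
    transformed = transformed[kept]
    sample_table = sample_table.loc[kept]

    sample_table = impute_rin(sample_table)
    covars = DE_COVARIATES if is_rna else DA_COVARIATES
    include_batch = contrast.kind == "diagnosis"
    base_design = build_design(
        sample_table, voi, covariates=covars, include_batch=include_batch
    )
    if cfg.use_noise_pc:
        pc_noise = compute_noise_pc(transformed, base_design)
        design = build_design(
            sample_table, voi, covariates=covars,
            pc_noise=pc_noise, include_batch=include_batch,
        )
    else:
        design = base_design

    if is_rna:
        _, sf = transform_counts(pb.values)
        res = fit_nb_glm_wald(pb.values, design, sf.to_numpy())
    else:
        res, residuals = fit_lm_wald(transformed, design, already_log=True)
        norm_check = check_residual_normality(residuals)
        res.attrs["residual_normality_rejected_fraction"] = norm_check.attrs[
            "rejected_fraction"
        ]

    res["fdr"] = bh_adjust(res["p_value"])
    res["significant"] = res["fdr"] <= cfg.fdr_threshold
    res["n_samples_used"] = pb.n_samples
    res["cell_type"] = pb.sample_meta["cell_type"].iloc[0]
    res["modality"] = pb.modality
    res["contrast"] = contrast.label
    return res.reset_index(drop=True)
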