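"""Covariate selection, hidden-noise PC estimation, and design matrices.

The covariate model is selected once on the full (across-cell-type)
pseudobulk: counts are variance-stabilized, PCA is run, and each candidate
covariate is tested for association with the first 10 principal components
(Pearson correlation for continuous covariates, one-way ANOVA of PC scores
by level for categoricals — the univariate equivalent of a canonical
correlation screen). One hidden-noise covariate (``PC_noise``) is then
estimated as the first principal component of the expression residuals
after regressing out the selected covariates and the variable of interest,
and enters the final differential-testing model:

    ~ variable_of_interest + Sex + Age + pH + RIN + PMI + lib_batch + PC_noise

The variance-stabilizing transform here is median-of-ratios size factors
followed by log2(count / size_factor + 1): closed-form, rank-preserving,
and exactly testable, in place of a toolkit-internal VST.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "CovariateReport",
    "transform_counts",
    "pca_scores",
    "associate_covariates_with_pcs",
    "impute_rin",
    "compute_noise_pc",
    "remove_outliers_iterative",
    "build_design",
]

CONTINUOUS_COVARIATES = ("age", "brain_pH", "pmi", "rin")
CATEGORICAL_COVARIATES = ("sex", "lib_batch")


@dataclass
class DesignMatrix:
    """Numeric samples x columns design with provenance.

    Columns: intercept, the 0/1 variable of interest, covariates
    (continuous covariates centered; sex coded M=1; lib_batch one-hot with
    the first level dropped), and PC_noise when supplied. Always full
    column rank (construction fails otherwise).
    """

    matrix: pd.DataFrame
    variable_of_interest: str
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def array(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def voi_index(self) -> int:
        return list(self.matrix.columns).index(self.variable_of_interest)


@dataclass
class CovariateReport:
    """Association of each candidate covariate with the leading PCs."""

    table: pd.DataFrame  # covariate, pc, statistic, p_value, selected
    selected: list[str]
    alpha: float


def transform_counts(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Variance-stabilize pseudobulk counts (features x samples).

    Size factor per sample = median over all-positive features of
    count / geometric-mean(feature); transformed value =
    log2(count / size_factor + 1). Falls back to total-count scaling
    (normalized so factors average 1) when no feature is positive in every
    sample.
    """
    counts = values.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        logmeans = np.log(counts[all_positive]).mean(axis=1)
        ratios = np.log(counts[all_positive]) - logmeans[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no feature with all-positive counts; falling back to total-count size factors"
        )
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts cannot be size-factored")
        size_factors = totals / np.exp(np.mean(np.log(totals)))
    transformed = np.log2(counts / size_factors[None, :] + 1.0)
    sf = pd.Series(size_factors, index=values.columns, name="size_factor")
    return pd.DataFrame(transformed, index=values.index, columns=values.columns), sf


def pca_scores(
    matrix: np.ndarray | pd.DataFrame,
    n_pcs: int,
    center: bool = True,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """PC scores of a samples x features matrix via SVD.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so scores are deterministic. Returns
    ``(scores, explained_variance_ratio)``; zero-variance components yield
    zero scores and zero explained variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    n_pcs = min(n_pcs, min(X.shape) - (1 if center else 0))
    n_pcs = max(n_pcs, 1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S[None, :] * flip[None, :]
    total_var = np.sum(np.asarray(X) ** 2)
    evr = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    return scores, evr


def associate_covariates_with_pcs(
    scores: np.ndarray,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
    categorical: tuple[str, ...] = CATEGORICAL_COVARIATES,
    n_pcs: int = 10,
) -> CovariateReport:
    """Screen covariates against the first ``n_pcs`` PCs.

    Continuous covariates: Pearson correlation with each PC and its t-test
    p-value. Categorical covariates: one-way ANOVA F-test of the PC scores
    grouped by level. A covariate is selected when its minimum p-value over
    the screened PCs is <= ``alpha``. Constant covariates are excluded with
    a warning.
    """
    if scores.shape[0] < 3:
        raise ValueError("covariate screening needs at least 3 samples")
    n_pcs = min(n_pcs, scores.shape[1], scores.shape[0] - 1)
    rows = []
    for cov in continuous:
        x = cohort[cov].to_numpy(dtype=float)
        if np.nanstd(x) == 0 or np.isnan(x).all():
            warnings.warn(f"continuous covariate {cov!r} is constant; excluded")
            continue
        ok = ~np.isnan(x)
        for j in range(n_pcs):
            r, p = stats.pearsonr(x[ok], scores[ok, j])
            rows.append({"covariate": cov, "pc": j + 1, "statistic": r, "p_value": p})
    for cov in categorical:
        levels = cohort[cov].astype(str)
        if levels.nunique() < 2:
            warnings.warn(f"categorical covariate {cov!r} has a single level; excluded")
            continue
        for j in range(n_pcs):
            groups = [scores[(levels == lv).to_numpy(), j] for lv in sorted(levels.unique())]
            if any(len(g) < 1 for g in groups):
                continue
            f, p = stats.f_oneway(*groups)
            rows.append({"covariate": cov, "pc": j + 1, "statistic": f, "p_value": p})
    table = pd.DataFrame(rows, columns=["covariate", "pc", "statistic", "p_value"])
    selected = []
    if len(table):
        min_p = table.groupby("covariate")["p_value"].min()
        selected = sorted(min_p.index[min_p <= alpha])
        table["selected"] = table["covariate"].isin(selected)
    return CovariateReport(table=table, selected=selected, alpha=alpha)


def impute_rin(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill missing RIN values with the cohort median of observed RIN."""
    observed = cohort["rin"].dropna()
    if observed.empty:
        raise ValueError("cannot impute RIN: all values missing")
    out = cohort.copy()
    out["rin"] = out["rin"].fillna(float(observed.median()))
    return out


def compute_noise_pc(
    transformed: pd.DataFrame,
    design: DesignMatrix,
) -> np.ndarray:
    """First PC of expression residuals after regressing out the design.

    ``transformed`` is features x samples; every feature is residualized
    against the design column space (including the variable of interest),
    and the first principal component of the residual matrix, standardized
    to unit variance, is returned. By construction the residuals — and hence
    the returned scores — are orthogonal to every design column.
    """
    X = design.array()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few samples to estimate a noise PC beyond the design")
    Y = transformed.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    if np.abs(R).max() < 1e-10:
        warnings.warn("residual matrix is numerically zero; PC_noise set to zeros")
        return np.zeros(n)
    # no extra centering: residuals already have zero mean via the intercept,
    # and centering would break exact orthogonality to the design
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    flip = np.sign(Vt[0, np.abs(Vt[0]).argmax()]) or 1.0
    pc = U[:, 0] * S[0] * flip
    sd = pc.std(ddof=1)
    return pc / sd if sd > 0 else pc


def remove_outliers_iterative(
    transformed: pd.DataFrame,
    sd_threshold: float = 3.0,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop samples > ``sd_threshold`` SDs from the PC1 mean.

    ``transformed`` is features x samples. Each round recomputes PCA on the
    remaining samples and removes those whose PC1 score deviates from the
    score mean by more than ``sd_threshold`` sample SDs (ddof=1); the loop
    stops when a round removes nothing or fewer than 3 samples remain.
    Returns the kept sample ids and a per-round removal log.
    """
    kept = list(transformed.columns)
    log: list[dict] = []
    iteration = 0
    while len(kept) >= 3:
        iteration += 1
        scores, _ = pca_scores(transformed[kept].to_numpy().T, n_pcs=1)
        pc1 = scores[:, 0]
        sd = pc1.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(pc1 - pc1.mean())
        removed = [s for s, d in zip(kept, dev) if d > sd_threshold * sd]
        if not removed:
            break
        log.append({"iteration": iteration, "removed": removed, "sd": float(sd)})
        kept = [s for s in kept if s not in removed]
    return kept, log


def build_design(
    sample_table: pd.DataFrame,
    variable_of_interest: str,
    covariates: tuple[str, ...] = ("sex", "age", "brain_pH", "rin", "pmi", "lib_batch"),
    pc_noise: np.ndarray | None = None,
    include_batch: bool = True,
) -> DesignMatrix:
    """Assemble the differential-testing design matrix.

    ``sample_table`` is indexed by sample id and must contain a 0/1 column
    named ``variable_of_interest`` plus the covariate columns. Continuous
    covariates are centered; sex is coded M=1; lib_batch is one-hot with
    the reference (first sorted) level dropped. ``include_batch=False``
    drops lib_batch — required for genetic-risk contrasts, where batch cells
    are too sparse to support a categorical term. Rank deficiency raises
    with the offending columns named.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sample_table))}
    voi = sample_table[variable_of_interest].to_numpy(dtype=float)
    if not np.isin(voi, (0.0, 1.0)).all():
        raise ValueError(f"variable of interest {variable_of_interest!r} must be 0/1")
    cols[variable_of_interest] = voi
    provenance = {"intercept": "constant", variable_of_interest: "variable_of_interest"}
    for cov in covariates:
        if cov == "lib_batch":
            if not include_batch:
                logger.info("lib_batch omitted from the design (risk-contrast model)")
                continue
            levels = sorted(sample_table["lib_batch"].astype(str).unique())
            for lv in levels[1:]:
                name = f"lib_batch[{lv}]"
                cols[name] = (sample_table["lib_batch"].astype(str) == lv).to_numpy(float)
                provenance[name] = "categorical covariate (reference dropped)"
        elif cov == "sex":
            cols["sex"] = (sample_table["sex"] == "M").to_numpy(float)
            provenance["sex"] = "categorical covariate (M=1)"
        else:
            x = sample_table[cov].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"covariate {cov!r} has missing values; impute first")
            cols[cov] = x - x.mean()
            provenance[cov] = "continuous covariate (centered)"
    if pc_noise is not None:
        pc_noise = np.asarray(pc_noise, dtype=float)
        if len(pc_noise) != len(sample_table):
            raise ValueError("PC_noise length does not match sample count")
        cols["PC_noise"] = pc_noise
        provenance["PC_noise"] = "hidden-noise principal component"
    matrix = pd.DataFrame(cols, index=sample_table.index)
    X = matrix.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [c for c, d in zip(matrix.columns, diag) if d < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=matrix, variable_of_interest=variable_of_interest, provenance=provenance)
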