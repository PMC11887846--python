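"""Synthetic cohort and count generators.

Emulates the statistical structure of a postmortem-brain single-nucleus
multi-omic case/control study: a cohort of donors with demographic and
technical covariates, per-donor polygenic risk scores correlated with a
latent disease liability, negative-binomial pseudobulk expression counts per
cell type, log-normal chromatin-accessibility gene scores, and the genomic
annotations (genes, fixed-width peaks, motif matrix, gene sets) the
downstream enrichment steps need.

Planted effects (case/control log2 fold changes, risk-score effects, one
hidden batch-like factor, library-batch offsets) are recorded in a
:class:`SimulationTruth` before any noise is drawn, so parameter-recovery
tests can score every downstream stage without re-simulation.

Cohort covariate defaults follow the study population the pipeline targets:
age ~ N(54.27, 13.64) years, postmortem interval ~ N(33.90, 14.82) hours
truncated at 0, brain pH ~ N(6.60, 0.24), 38% female, and a case mix of
schizophrenia / schizoaffective / MDD / bipolar in proportions 38:7:7:5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import (
    GeneAnnotation,
    GeneSetCollection,
    MotifAnnotation,
    NucleusMatrix,
    PeakSet,
    PseudobulkAssay,
)

__all__ = [
    "DonorRecord",
    "TruthSpec",
    "SimulationTruth",
    "generate_cohort",
    "generate_prs",
    "generate_expression_counts",
    "generate_nucleus_counts",
    "generate_gene_scores",
    "generate_annotations",
    "hidden_sd_for_snr",
]

LN2 = np.log(2.0)

# cohort covariate distributions (study-population defaults)
AGE_MEAN, AGE_SD = 54.27, 13.64
PMI_MEAN, PMI_SD = 33.90, 14.82
PH_MEAN, PH_SD = 6.60, 0.24
FEMALE_FRACTION = 0.38
CASE_FRACTION = 57 / 92
DIAGNOSES = ("schizophrenia", "schizoaffective", "MDD", "bipolar")
DIAGNOSIS_WEIGHTS = np.array([38, 7, 7, 5]) / 57


@dataclass(frozen=True)
class DonorRecord:
    """One donor's diagnosis, covariates and polygenic risk scores."""

    donor_id: str
    disease_status: str  # "case" | "control"
    diagnosis: str
    sex: str  # "F" | "M"
    age: float  # years
    brain_pH: float
    pmi: float  # hours
    rin: float | None  # RNA integrity number, may be missing
    lib_batch: str
    prs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 0 < self.brain_pH < 14:
            raise ValueError("brain pH outside (0, 14)")
        if self.pmi < 0:
            raise ValueError("PMI must be non-negative")


@dataclass
class TruthSpec:
    """Parameters of the planted signal in synthetic counts / gene scores.

    Effects are log2 fold changes. ``status_frac`` of genes carry a
    case-vs-control effect of magnitude ``status_lfc`` (random sign);
    ``risk_frac`` carry a PRS effect scaled so that donors one PRS standard
    deviation apart differ by ``risk_lfc``/2 log2 units (i.e. the top and
    bottom of the PRS distribution differ by roughly ``risk_lfc`` or more).
    ``hidden_sd`` is the per-gene loading scale of one hidden donor-level
    factor; ``batch_sd`` the scale of per-gene library-batch offsets;
    ``covariate_sd`` the scale of per-gene coefficients on the standardized
    known covariates (age, pH, PMI, RIN, sex).
    """

    status_frac: float = 0.1
    status_lfc: float = 1.0
    risk_frac: float = 0.1
    risk_lfc: float = 1.0
    risk_trait: str = "schizophrenia"
    dispersion: float = 0.1
    hidden_sd: float = 0.0
    batch_sd: float = 0.2
    covariate_sd: float = 0.05
    base_log2_range: tuple[float, float] = (3.0, 9.0)
    libsize_log2_range: tuple[float, float] = (-1.0, 1.0)  # >= 4-fold spread
    score_noise_sd: float = 0.5  # log2-scale noise of gene scores

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for frac in (self.status_frac, self.risk_frac):
            if not 0 <= frac <= 1:
                raise ValueError("effect fractions must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Planted ground truth, recorded before noise is drawn."""

    gene_effects: pd.DataFrame  # cell_type, gene_id, lfc_status, lfc_risk, hidden_loading
    donor_hidden: pd.Series  # hidden factor value per donor
    risk_trait: str
    seed: int
    params: dict

    def effects_for(self, cell_type: str) -> pd.DataFrame:
        df = self.gene_effects
        return df[df["cell_type"] == cell_type].set_index("gene_id")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_effects": self.gene_effects.to_dict(orient="list"),
            "donor_hidden": self.donor_hidden.to_dict(),
            "risk_trait": self.risk_trait,
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def hidden_sd_for_snr(snr: float, dispersion: float, mean_count: float) -> float:
    """Loading scale giving a hidden-factor SNR on the log2 count scale.

    The sampling variance of log2 counts around a negative-binomial mean mu
    is approximately (1/mu + alpha) / ln(2)^2 (delta method); a loading of
    sqrt(snr * that) makes the hidden factor contribute ``snr`` times the
    sampling variance per gene.
    """
    noise_var = (1.0 / mean_count + dispersion) / LN2**2
    return float(np.sqrt(snr * noise_var))


# ---------------------------------------------------------------------------
# cohort and PRS


def generate_cohort(
    n_donors: int,
    case_fraction: float = CASE_FRACTION,
    seed: int = 0,
    n_batches: int = 4,
) -> pd.DataFrame:
    """Draw a donor cohort with the study-population covariate distributions.

    Exactly one donor's RIN is set missing whenever ``n_donors >= 2`` so the
    median-imputation path is always exercised. Library batches are assigned
    round-robin over ``n_batches``.
    """
    if not 0 <= case_fraction <= 1:
        raise ValueError(f"case_fraction must lie in [0, 1], got {case_fraction}")
    if n_donors < 0:
        raise ValueError("n_donors must be non-negative")
    rng = np.random.default_rng(seed)
    n_cases = int(round(n_donors * case_fraction))
    status = np.array(["case"] * n_cases + ["control"] * (n_donors - n_cases))
    rng.shuffle(status)
    diagnosis = np.where(
        status == "case",
        rng.choice(DIAGNOSES, size=n_donors, p=DIAGNOSIS_WEIGHTS),
        "control",
    )
    age = rng.normal(AGE_MEAN, AGE_SD, n_donors)
    age = np.clip(age, 18.0, None)  # adult cohort
    pmi = rng.normal(PMI_MEAN, PMI_SD, n_donors)
    while (pmi < 0).any():  # truncate at 0 by redrawing
        pmi[pmi < 0] = rng.normal(PMI_MEAN, PMI_SD, int((pmi < 0).sum()))
    ph = np.clip(rng.normal(PH_MEAN, PH_SD, n_donors), 5.5, 7.5)
    sex = np.where(rng.random(n_donors) < FEMALE_FRACTION, "F", "M")
    rin = np.clip(rng.normal(7.0, 1.0, n_donors), 1.0, 10.0)
    cohort = pd.DataFrame(
        {
            "donor_id": [f"D{i:03d}" for i in range(n_donors)],
            "disease_status": status,
            "diagnosis": diagnosis,
            "sex": sex,
            "age": age,
            "brain_pH": ph,
            "pmi": pmi,
            "rin": rin,
            "lib_batch": [f"batch{i % n_batches}" for i in range(n_donors)],
        }
    )
    if n_donors >= 2:
        cohort.loc[int(rng.integers(n_donors)), "rin"] = np.nan
    return cohort


def generate_prs(
    cohort: pd.DataFrame,
    trait: str,
    liability_correlation: float = 0.3,
    seed: int = 0,
    prs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add a standardized PRS column for ``trait`` to a per-donor PRS table.

    A latent disease liability is drawn consistent with each donor's status
    under a liability-threshold model (cases above the threshold, controls
    below); the PRS is ``rho * liability + sqrt(1 - rho^2) * noise``,
    standardized to mean 0, SD 1. With ``rho < 1`` both extreme-PRS tails
    contain cases and controls, as in real cohorts.
    """
    rho = liability_correlation
    if not -1 <= rho <= 1:
        raise ValueError("liability_correlation must lie in [-1, 1]")
    if prs is None:
        prs = pd.DataFrame({"donor_id": cohort["donor_id"].to_numpy()})
    if trait in prs.columns:
        raise ValueError(f"trait {trait!r} already present in the PRS table")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    is_case = (cohort["disease_status"] == "case").to_numpy()
    case_frac = is_case.mean() if n else 0.5
    case_frac = min(max(case_frac, 1e-6), 1 - 1e-6)
    thr = stats.norm.ppf(1 - case_frac)
    # inverse-CDF sampling of the truncated liability
    u = rng.random(n)
    upper_mass = stats.norm.sf(thr)
    liability = np.where(
        is_case,
        stats.norm.isf(u * upper_mass),  # above threshold
        stats.norm.ppf(u * (1 - upper_mass)),  # below threshold
    )
    raw = rho * liability + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    if n > 1 and raw.std(ddof=0) > 0:
        raw = (raw - raw.mean()) / raw.std(ddof=0)
    out = prs.copy()
    out[trait] = raw
    return out


# ---------------------------------------------------------------------------
# planted effects


def _draw_effects(
    rng: np.random.Generator,
    cell_types: list[str],
    gene_ids: list[str],
    spec: TruthSpec,
) -> pd.DataFrame:
    """Per (cell type, gene) planted effects with random signs."""
    rows = []
    n_genes = len(gene_ids)
    for ct in cell_types:
        lfc_status = np.zeros(n_genes)
        lfc_risk = np.zeros(n_genes)
        n_status = int(round(spec.status_frac * n_genes))
        n_risk = int(round(spec.risk_frac * n_genes))
        idx_status = rng.choice(n_genes, n_status, replace=False)
        idx_risk = rng.choice(n_genes, n_risk, replace=False)
        lfc_status[idx_status] = spec.status_lfc * rng.choice([-1.0, 1.0], n_status)
        lfc_risk[idx_risk] = spec.risk_lfc * rng.choice([-1.0, 1.0], n_risk)
        loading = spec.hidden_sd * rng.standard_normal(n_genes)
        rows.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "gene_id": gene_ids,
                    "lfc_status": lfc_status,
                    "lfc_risk": lfc_risk,
                    "hidden_loading": loading,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _covariate_design(cohort: pd.DataFrame) -> np.ndarray:
    """Standardized known covariates (age, pH, PMI, RIN, sex) as columns."""
    cols = []
    for c in ("age", "brain_pH", "pmi", "rin"):
        x = cohort[c].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x) if np.isfinite(np.nanmean(x)) else 0.0, x)
        sd = x.std(ddof=0)
        cols.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
    cols.append((cohort["sex"] == "M").to_numpy(float) - (cohort["sex"] == "M").mean())
    return np.column_stack(cols)


def _log2_mean_matrix(
    cohort: pd.DataFrame,
    effects: pd.DataFrame,
    base_log2: np.ndarray,
    libsize_log2: np.ndarray,
    hidden: np.ndarray,
    batch_offsets: pd.DataFrame,
    cov_coefs: np.ndarray,
    cov_design: np.ndarray,
    prs: np.ndarray,
) -> np.ndarray:
    """Genes x donors log2 mean surface from all planted components."""
    status = (cohort["disease_status"] == "case").to_numpy(float)
    lfc_status = effects["lfc_status"].to_numpy()[:, None]
    lfc_risk = effects["lfc_risk"].to_numpy()[:, None]
    loading = effects["hidden_loading"].to_numpy()[:, None]
    log2mu = (
        base_log2[:, None]
        + libsize_log2[None, :]
        + lfc_status * status[None, :]
        + lfc_risk * (prs[None, :] / 2.0)
        + loading * hidden[None, :]
        + cov_coefs @ cov_design.T
    )
    batch_idx = batch_offsets.columns.get_indexer(cohort["lib_batch"])
    log2mu += batch_offsets.to_numpy()[:, batch_idx]
    return log2mu


def generate_expression_counts(
    cohort: pd.DataFrame,
    cell_types: list[str],
    n_genes: int,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
    prs: pd.DataFrame | None = None,
    n_cells_range: tuple[int, int] = (50, 500),
    hidden_factor: np.ndarray | None = None,
    n_cells: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, PseudobulkAssay], SimulationTruth]:
    """Negative-binomial pseudobulk RNA counts per cell type.

    Per cell type and donor, counts for gene g are NB with
    ``log2 mean = baseline_g + library-size offset + status effect +
    PRS effect + hidden factor + batch offset + covariate effects`` and the
    dispersion in ``truth_spec``. Library-size offsets span at least 4-fold.
    Returns one :class:`PseudobulkAssay` per cell type plus the recorded
    :class:`SimulationTruth`.
    """
    spec = truth_spec or TruthSpec()
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    donors = cohort["donor_id"].to_numpy()
    batches = sorted(cohort["lib_batch"].unique())

    effects = _draw_effects(rng, list(cell_types), gene_ids, spec)
    if hidden_factor is not None:
        hidden = np.asarray(hidden_factor, dtype=float)
        if hidden.shape != (len(cohort),):
            raise ValueError("hidden_factor must have one value per donor")
    else:
        hidden = rng.standard_normal(len(cohort))
    cov_design = _covariate_design(cohort)
    if prs is not None and spec.risk_trait in prs.columns:
        prs_vec = (
            prs.set_index("donor_id")[spec.risk_trait].reindex(donors).to_numpy(dtype=float)
        )
    else:
        prs_vec = np.zeros(len(cohort))

    truth = SimulationTruth(
        gene_effects=effects,
        donor_hidden=pd.Series(hidden, index=donors, name="hidden_factor"),
        risk_trait=spec.risk_trait,
        seed=seed,
        params=asdict(spec),
    )

    assays: dict[str, PseudobulkAssay] = {}
    lo, hi = spec.base_log2_range
    llo, lhi = spec.libsize_log2_range
    for ct in cell_types:
        eff = truth.effects_for(ct).loc[gene_ids]
        base_log2 = rng.uniform(lo, hi, n_genes)
        # evenly spaced then shuffled: the stated fold-spread is guaranteed
        libsize_log2 = rng.permutation(np.linspace(llo, lhi, len(cohort)))
        batch_offsets = pd.DataFrame(
            spec.batch_sd * rng.standard_normal((n_genes, len(batches))), columns=batches
        )
        cov_coefs = spec.covariate_sd * rng.standard_normal((n_genes, cov_design.shape[1]))
        log2mu = _log2_mean_matrix(
            cohort, eff, base_log2, libsize_log2, hidden, batch_offsets,
            cov_coefs, cov_design, prs_vec,
        )
        mu = 2.0**log2mu
        r = 1.0 / spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        nc = (
            np.asarray(n_cells[ct], dtype=int)
            if n_cells is not None
            else rng.integers(n_cells_range[0], n_cells_range[1] + 1, len(cohort))
        )
        sample_ids = [f"{d}|{ct}" for d in donors]
        assays[ct] = PseudobulkAssay(
            values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
            sample_meta=pd.DataFrame(
                {"donor_id": donors, "cell_type": ct, "n_cells": nc},
                index=sample_ids,
            ),
            modality="rna_counts",
        )
    return assays, truth


def generate_nucleus_counts(
    cohort: pd.DataFrame,
    cell_types: list[str],
    n_genes: int,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
    nuclei_per_donor: tuple[int, int] = (20, 60),
) -> tuple[NucleusMatrix, SimulationTruth]:
    """Per-nucleus Poisson counts whose donor/cell-type sums are NB pseudobulk.

    For each (donor, cell type) a gene-level rate is drawn from a gamma
    mixing distribution (so the summed counts are negative binomial) and
    split across nuclei as independent Poisson draws. Used to exercise QC
    and aggregation; differential testing operates on the aggregated level.
    """
    spec = truth_spec or TruthSpec()
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    effects = _draw_effects(rng, list(cell_types), gene_ids, spec)
    hidden = rng.standard_normal(len(cohort))
    donors = cohort["donor_id"].to_numpy()
    truth = SimulationTruth(
        gene_effects=effects,
        donor_hidden=pd.Series(hidden, index=donors, name="hidden_factor"),
        risk_trait=spec.risk_trait,
        seed=seed,
        params=asdict(spec),
    )
    blocks, meta_rows = [], []
    status = (cohort["disease_status"] == "case").to_numpy(float)
    nucleus_counter = 0
    for ct in cell_types:
        eff = truth.effects_for(ct).loc[gene_ids]
        # modest per-nucleus depth so pseudobulk sums stay in a bulk-like range
        base_log2 = rng.uniform(1.0, 5.0, n_genes)
        log2mu = (
            base_log2[:, None]
            + eff["lfc_status"].to_numpy()[:, None] * status[None, :]
            + eff["hidden_loading"].to_numpy()[:, None] * hidden[None, :]
        )
        mu = 2.0**log2mu  # genes x donors pseudobulk mean
        shape = 1.0 / spec.dispersion
        for d_idx, donor in enumerate(donors):
            n_nuc = int(rng.integers(*nuclei_per_donor))
            lam = rng.gamma(shape, spec.dispersion * mu[:, d_idx])  # NB mixing rate
            nuc_counts = rng.poisson(lam[None, :] / n_nuc, size=(n_nuc, n_genes))
            blocks.append(sp.csr_matrix(nuc_counts))
            mito = rng.beta(2, 30, n_nuc)
            for j in range(n_nuc):
                meta_rows.append(
                    {
                        "nucleus_id": f"N{nucleus_counter:07d}",
                        "donor_id": donor,
                        "cell_type": ct,
                        "total_counts": int(nuc_counts[j].sum()),
                        "n_features_detected": int((nuc_counts[j] > 0).sum()),
                        "mito_fraction": float(mito[j]),
                    }
                )
                nucleus_counter += 1
    nm = NucleusMatrix(
        counts=sp.vstack(blocks).tocsr(),
        nucleus_meta=pd.DataFrame(meta_rows),
        feature_ids=gene_ids,
    )
    return nm, truth


def generate_gene_scores(
    cohort: pd.DataFrame,
    cell_types: list[str],
    n_genes: int,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
    prs: pd.DataFrame | None = None,
    n_cells_range: tuple[int, int] = (50, 500),
    hidden_factor: np.ndarray | None = None,
    n_cells: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, PseudobulkAssay], SimulationTruth]:
    """Log-normal chromatin-accessibility gene scores per cell type.

    The per-sample log2 signal is ``baseline + planted effects + Gaussian
    noise``; the emitted (un-normalized) value is ``2**signal * n_cells`` so
    that dividing by the number of aggregated cells downstream recovers the
    per-cell signal. Values are strictly positive, not counts.
    """
    spec = truth_spec or TruthSpec()
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    donors = cohort["donor_id"].to_numpy()
    batches = sorted(cohort["lib_batch"].unique())
    effects = _draw_effects(rng, list(cell_types), gene_ids, spec)
    if hidden_factor is not None:
        hidden = np.asarray(hidden_factor, dtype=float)
        if hidden.shape != (len(cohort),):
            raise ValueError("hidden_factor must have one value per donor")
    else:
        hidden = rng.standard_normal(len(cohort))
    cov_design = _covariate_design(cohort)
    if prs is not None and spec.risk_trait in prs.columns:
        prs_vec = (
            prs.set_index("donor_id")[spec.risk_trait].reindex(donors).to_numpy(dtype=float)
        )
    else:
        prs_vec = np.zeros(len(cohort))
    truth = SimulationTruth(
        gene_effects=effects,
        donor_hidden=pd.Series(hidden, index=donors, name="hidden_factor"),
        risk_trait=spec.risk_trait,
        seed=seed,
        params=asdict(spec),
    )
    assays: dict[str, PseudobulkAssay] = {}
    for ct in cell_types:
        eff = truth.effects_for(ct).loc[gene_ids]
        base_log2 = rng.uniform(2.0, 6.0, n_genes)
        batch_offsets = pd.DataFrame(
            spec.batch_sd * rng.standard_normal((n_genes, len(batches))), columns=batches
        )
        cov_coefs = spec.covariate_sd * rng.standard_normal((n_genes, cov_design.shape[1]))
        log2sig = _log2_mean_matrix(
            cohort, eff, base_log2, np.zeros(len(cohort)), hidden, batch_offsets,
            cov_coefs, cov_design, prs_vec,
        )
        log2sig += spec.score_noise_sd * rng.standard_normal(log2sig.shape)
        nc = (
            np.asarray(n_cells[ct], dtype=int)
            if n_cells is not None
            else rng.integers(n_cells_range[0], n_cells_range[1] + 1, len(cohort))
        )
        raw = 2.0**log2sig * nc[None, :]
        sample_ids = [f"{d}|{ct}" for d in donors]
        assays[ct] = PseudobulkAssay(
            values=pd.DataFrame(raw, index=gene_ids, columns=sample_ids),
            sample_meta=pd.DataFrame(
                {"donor_id": donors, "cell_type": ct, "n_cells": nc},
                index=sample_ids,
            ),
            modality="atac_genescore",
            normalized=False,
        )
    return assays, truth


def generate_cell_compositions(
    cohort: pd.DataFrame,
    cell_types: list[str],
    seed: int = 0,
    total_cells: dict[str, tuple[int, int]] | None = None,
    concentration: float = 50.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-donor nucleus counts per cell type, shared across modalities.

    One cohort-level cell-type composition is drawn from a Dirichlet, each
    donor's composition from a Dirichlet centred on it (``concentration``
    controls donor-to-donor spread), and each modality gets its own total
    nucleus count per donor (RNA deeper than ATAC, as in paired single-
    nucleus assays). Because both modalities share the donor composition,
    donor-wise cell-type proportions correlate strongly across modalities.
    Returns ``{modality: {cell_type: counts-per-donor array}}``.
    """
    rng = np.random.default_rng(seed)
    totals = total_cells or {"rna": (4000, 12000), "atac": (1500, 6000)}
    k = len(cell_types)
    base = rng.dirichlet(np.full(k, 5.0))
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in totals}
    donor_props = rng.dirichlet(np.maximum(base * concentration, 1e-3), size=len(cohort))
    for modality, (lo, hi) in totals.items():
        tot = rng.integers(lo, hi + 1, len(cohort))
        # modality-specific capture noise around the donor composition
        props = np.vstack(
            [rng.dirichlet(np.maximum(p * 4 * concentration, 1e-3)) for p in donor_props]
        )
        counts = np.maximum(np.round(props * tot[:, None]).astype(int), 1)
        for j, ct in enumerate(cell_types):
            out[modality][ct] = counts[:, j]
    return out


# ---------------------------------------------------------------------------
# annotations

PEAK_WIDTH = 501  # fixed-width merged peaks
CHROMOSOMES = ("chr1", "chr2", "chr3", "chr4")


def generate_annotations(
    n_genes: int,
    n_peaks: int,
    n_motifs: int,
    n_sets: int,
    seed: int = 0,
    set_size_range: tuple[int, int] = (10, 50),
) -> tuple[GeneAnnotation, PeakSet, MotifAnnotation, GeneSetCollection]:
    """Gene bodies, 501-bp peaks, a binary motif matrix, and gene sets.

    Genes are laid out along four chromosomes with random lengths and gaps;
    each gene receives one peak inside its promoter window (2 kb upstream to
    500 bp downstream of the TSS, strand-aware) as long as peaks remain;
    extra peaks land uniformly across the spanned region. Motif presence is
    Bernoulli with a per-motif rate drawn from U(0.02, 0.3).
    """
    if min(n_genes, n_peaks, n_motifs, n_sets) < 0:
        raise ValueError("annotation counts must be non-negative")
    rng = np.random.default_rng(seed)
    gene_rows = []
    pos = {c: 10_000 for c in CHROMOSOMES}
    for i in range(n_genes):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        length = int(rng.integers(2_000, 50_000))
        gap = int(rng.integers(10_000, 100_000))
        start = pos[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"G{i:05d}", chrom, start, start + length, strand))
        pos[chrom] = start + length
    genes = GeneAnnotation(
        table=pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        ).set_index("gene_id")
    )

    if n_peaks < n_genes:
        warnings.warn(
            f"{n_peaks} peaks for {n_genes} genes: some genes will lack a promoter peak"
        )
    peak_rows = []
    tss = genes.tss()
    half = PEAK_WIDTH // 2
    for i in range(n_peaks):
        if i < n_genes:
            gid = genes.gene_ids[i]
            t = int(tss.loc[gid])
            sign = 1 if genes.table.loc[gid, "strand"] == "+" else -1
            # centered inside the strand-aware promoter window
            center = t - sign * 750
            chrom = genes.table.loc[gid, "chrom"]
        else:
            chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
            center = int(rng.integers(10_000, max(pos[chrom], 20_000)))
        start = max(0, center - half)
        peak_rows.append((f"P{i:05d}", chrom, start, start + PEAK_WIDTH))
    peaks = PeakSet(
        table=pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"]).set_index(
            "peak_id"
        )
    )

    rates = rng.uniform(0.02, 0.3, n_motifs)
    motif_mat = (rng.random((n_peaks, n_motifs)) < rates[None, :]).astype(int)
    motifs = MotifAnnotation(
        table=pd.DataFrame(
            motif_mat, index=peaks.peak_ids, columns=[f"M{j:03d}" for j in range(n_motifs)]
        )
    )

    gene_ids = genes.gene_ids
    sets: dict[str, tuple[str, list[str]]] = {}
    hi = min(set_size_range[1], max(1, n_genes))
    lo = min(set_size_range[0], hi)
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(gene_ids, size=size, replace=False))
        sets[f"S{s:03d}"] = (f"synthetic gene set {s}", list(members))
    return genes, peaks, motifs, GeneSetCollection(sets=sets)
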