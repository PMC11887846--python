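"""Enrichment, correlation networks, and cross-study comparisons.

Over-representation of gene sets (pathway stand-ins) and TF motifs uses the
exact upper-tail hypergeometric test with Benjamini-Hochberg adjustment.
Multi-omic correlation networks connect expression, accessibility, PRS and
status nodes by Spearman correlation (expression/accessibility features are
residualized against the known covariates first); edges keep nominal
p <= 0.05 with |rho| as weight. Cross-study comparison correlates per-gene
effect sizes between two result tables, cell type by cell type.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneAnnotation, GeneSetCollection, MotifAnnotation, PeakSet
from .differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeometric_enrichment",
    "pathway_enrichment",
    "motif_enrichment",
    "spearman_network",
    "cross_study_fc_correlation",
    "compare_proportions",
]


def hypergeometric_enrichment(
    selection: set[str] | list[str],
    universe: set[str] | list[str],
    sets: dict[str, list[str]] | GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per set.

    ``p = P(X >= k)`` for overlap k between the selection (size n) and a set
    of size K within a universe of size N; BH across sets. Sets are
    intersected with the universe before testing. An empty selection yields
    p = 1 everywhere.
    """
    if isinstance(sets, GeneSetCollection):
        sets = dict(sets.as_dict())
    universe = set(universe)
    selection = set(selection)
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    N, n = len(universe), len(selection)
    rows = []
    for set_id in sorted(sets):
        members = set(sets[set_id]) & universe
        K = len(members)
        k = len(members & selection)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {"set_id": set_id, "overlap": k, "set_size": K, "selection_size": n,
             "universe_size": N, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"])
        out["significant"] = out["fdr"] <= fdr_threshold
    return out


def _rank_for_direction(df: pd.DataFrame, direction: str) -> pd.DataFrame:
    sub = df[df["log2FC"] > 0] if direction == "up" else df[df["log2FC"] < 0]
    sub = sub.dropna(subset=["fdr"])
    sub = sub.assign(_abs_lfc=sub["log2FC"].abs())
    return sub.sort_values(
        ["fdr", "_abs_lfc", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )


def pathway_enrichment(
    diff_results: pd.DataFrame,
    gene_sets: GeneSetCollection | dict[str, list[str]],
    top_n: int = 250,
    min_genes: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of gene sets among the top differential genes.

    Per cell type and regulation direction, the ``top_n`` genes with the
    most significant up- (log2FC > 0) or down-regulation ranked by FDR
    (ties: larger |log2FC|, then gene id) are tested against the universe of
    genes evaluated in that cell type. Directions with fewer than
    ``min_genes`` genes are skipped with a warning.
    """
    frames = []
    for cell_type, df in diff_results.groupby("cell_type"):
        universe = set(df["gene_id"])
        for direction in ("up", "down"):
            ranked = _rank_for_direction(df, direction)
            if len(ranked) < min_genes:
                warnings.warn(
                    f"{cell_type}/{direction}: only {len(ranked)} genes; skipped"
                )
                continue
            selection = set(ranked["gene_id"].head(top_n))
            enr = hypergeometric_enrichment(selection, universe, gene_sets, fdr_threshold)
            enr["cell_type"] = cell_type
            enr["direction"] = direction
            frames.append(enr)
    if not frames:
        return pd.DataFrame(
            columns=["set_id", "overlap", "set_size", "selection_size",
                     "universe_size", "p_value", "fdr", "significant",
                     "cell_type", "direction"]
        )
    return pd.concat(frames, ignore_index=True)


def promoter_peaks(
    gene_id: str,
    genes: GeneAnnotation,
    peaks: PeakSet,
    upstream: int = 2000,
    downstream: int = 500,
) -> list[str]:
    """Peaks overlapping the strand-aware promoter window of a gene."""
    rec = genes.table.loc[gene_id]
    tss = int(genes.tss().loc[gene_id])
    if rec["strand"] == "+":
        lo, hi = tss - upstream, tss + downstream + 1
    else:
        lo, hi = tss - downstream, tss + upstream + 1
    tab = peaks.table
    hit = (tab["chrom"] == rec["chrom"]) & (tab["start"] < hi) & (tab["end"] > lo)
    return sorted(tab.index[hit])


def motif_enrichment(
    gene_id: str,
    genes: GeneAnnotation,
    peaks: PeakSet,
    motifs: MotifAnnotation,
    upstream: int = 2000,
    downstream: int = 500,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """TF motifs over-represented in a gene's promoter peaks vs all peaks.

    Selection = peaks in the promoter window (default 2 kb upstream to
    500 bp downstream of the TSS, strand-aware); universe = all annotated
    peaks; one hypergeometric test per motif, BH-adjusted. A gene with no
    promoter peak returns an empty, flagged table.
    """
    prom = promoter_peaks(gene_id, genes, peaks, upstream, downstream)
    prom = [p for p in prom if p in motifs.table.index]
    out_cols = ["set_id", "overlap", "set_size", "selection_size",
                "universe_size", "p_value", "fdr", "significant"]
    if not prom:
        out = pd.DataFrame(columns=out_cols)
        out.attrs["no_promoter_peaks"] = True
        return out
    motif_sets = {
        m: list(motifs.table.index[motifs.table[m] == 1]) for m in motifs.motif_ids
    }
    out = hypergeometric_enrichment(prom, list(motifs.table.index), motif_sets, fdr_threshold)
    out.attrs["no_promoter_peaks"] = False
    out.attrs["gene_id"] = gene_id
    return out


def _residualize(values: np.ndarray, covariate_matrix: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``values`` on the covariates."""
    X = np.column_stack([np.ones(covariate_matrix.shape[0]), covariate_matrix])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def spearman_p_values(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (df = n - 2)."""
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def spearman_network(
    features: pd.DataFrame,
    node_meta: pd.DataFrame,
    covariate_matrix: np.ndarray | pd.DataFrame | None = None,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Multi-omic Spearman correlation network.

    ``features`` is samples x features; ``node_meta`` (indexed like the
    feature columns) carries ``modality`` in {expression, accessibility,
    prs, status} and optionally ``cell_type``. Expression and accessibility
    features are residualized against ``covariate_matrix`` before ranking;
    PRS and status nodes enter uncorrected. Edges keep pairs with nominal
    p <= ``p_threshold``; weight = |rho|, sign retained; constant features
    are excluded with a warning.
    """
    n = len(features)
    if n < 5:
        raise ValueError("network inference needs at least 5 samples")
    vals = features.to_numpy(dtype=float).copy()
    names = list(features.columns)
    correct = node_meta.loc[names, "modality"].isin(["expression", "accessibility"]).to_numpy()
    if covariate_matrix is not None and correct.any():
        cov = np.asarray(covariate_matrix, dtype=float)
        vals[:, correct] = _residualize(vals[:, correct], cov)
    keep = vals.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant features excluded from the network")
    vals = vals[:, keep]
    names = [f for f, k in zip(names, keep) if k]
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)  # average ranks for ties
    rho = np.corrcoef(ranks, rowvar=False)
    graph = nx.Graph()
    for f in names:
        meta = node_meta.loc[f]
        graph.add_node(
            f, modality=str(meta["modality"]),
            cell_type=str(meta.get("cell_type", "n/a")),
        )
    pmat = spearman_p_values(rho, n)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if pmat[i, j] <= p_threshold:
                r = float(rho[i, j])
                graph.add_edge(
                    names[i], names[j],
                    rho=r, p_value=float(pmat[i, j]),
                    sign=int(np.sign(r)), weight=abs(r),
                )
    return graph


def cross_study_fc_correlation(
    fc_table_a: pd.DataFrame,
    fc_table_b: pd.DataFrame,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of per-gene effect sizes between two studies.

    Both tables need columns gene_id, cell_type, log2FC. Returns the
    cell-type x cell-type correlation matrix (rows = study A) and the
    matching matrix of shared-gene counts; pairs with fewer than
    ``min_shared`` shared genes get NaN.
    """
    a_types = sorted(fc_table_a["cell_type"].unique())
    b_types = sorted(fc_table_b["cell_type"].unique())
    corr = pd.DataFrame(np.nan, index=a_types, columns=b_types)
    shared = pd.DataFrame(0, index=a_types, columns=b_types)
    a_piv = {ct: df.set_index("gene_id")["log2FC"].dropna()
             for ct, df in fc_table_a.groupby("cell_type")}
    b_piv = {ct: df.set_index("gene_id")["log2FC"].dropna()
             for ct, df in fc_table_b.groupby("cell_type")}
    for ca in a_types:
        for cb in b_types:
            common = a_piv[ca].index.intersection(b_piv[cb].index)
            shared.loc[ca, cb] = len(common)
            if len(common) >= min_shared:
                x = a_piv[ca].loc[common].to_numpy()
                y = b_piv[cb].loc[common].to_numpy()
                if x.std() > 0 and y.std() > 0:
                    corr.loc[ca, cb] = stats.pearsonr(x, y)[0]
    return corr, shared


def compare_proportions(
    props_a: pd.DataFrame,
    props_b: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compare donor-paired cell-type proportions between two modalities.

    Both inputs are donors x cell types with rows summing to 1. Per cell
    type, a two-sided Wilcoxon signed-rank test on the paired differences
    (zeros dropped; exact null for n <= 25, normal approximation with
    continuity correction above), BH-adjusted across cell types. Also
    returns the per-donor Pearson correlation of the two proportion vectors
    (its median summarizes cross-modality agreement).
    """
    donors = props_a.index.intersection(props_b.index)
    cell_types = props_a.columns.intersection(props_b.columns)
    a = props_a.loc[donors, cell_types]
    b = props_b.loc[donors, cell_types]
    rows = []
    for ct in cell_types:
        diff = (a[ct] - b[ct]).to_numpy(dtype=float)
        nz = diff[diff != 0]
        if len(nz) == 0:
            rows.append({"cell_type": ct, "statistic": np.nan, "p_value": 1.0,
                         "n_nonzero": 0, "all_zero": True})
            continue
        method = "exact" if len(nz) <= 25 else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        rows.append({"cell_type": ct, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "n_nonzero": len(nz),
                     "all_zero": False})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_value"])
    table["significant"] = table["fdr"] <= fdr_threshold
    donor_corr = pd.Series(
        {d: stats.pearsonr(a.loc[d].to_numpy(), b.loc[d].to_numpy())[0]
         for d in donors if a.loc[d].std() > 0 and b.loc[d].std() > 0},
        name="pearson_r",
    )
    return table, donor_corr
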