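"""Nucleus QC, pseudobulk aggregation, gene-activity scores, and filters.

Aggregation sums nucleus counts within each cell-type/donor pair (or per
donor for the "full" pseudobulk used in covariate selection), conserving
totals exactly. Gene-activity scores summarize peak-level chromatin
accessibility in a distance-weighted 100-kb window around each gene body
with an exponential decay kernel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GeneAnnotation, NucleusMatrix, PeakSet, PseudobulkAssay

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "qc_filter_nuclei",
    "aggregate_pseudobulk",
    "compute_gene_scores",
    "normalize_gene_scores",
    "filter_features",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-nucleus QC cutoffs.

    RNA nuclei are dropped when total counts < ``min_counts``, detected
    genes < ``min_genes``, or mitochondrial fraction >= ``max_mito``
    (all strict in the stated direction, so a nucleus sitting exactly on
    500 counts / 300 genes / 14.9% mito is kept). ATAC nuclei are dropped
    outside [``min_fragments``, ``max_fragments``] unique nuclear fragments
    or below a TSS enrichment of ``min_tss_enrichment``. After nucleus
    filtering, features detected in fewer than ``min_nuclei_per_feature``
    nuclei are removed.
    """

    min_counts: int = 500
    min_genes: int = 300
    max_mito: float = 0.15
    min_fragments: int = 1000
    max_fragments: int = 100_000
    min_tss_enrichment: float = 4.0
    min_nuclei_per_feature: int = 500


def qc_filter_nuclei(
    nm: NucleusMatrix,
    thresholds: QCThresholds | None = None,
    modality: str = "rna",
) -> NucleusMatrix:
    """Apply per-nucleus QC, then drop features detected in too few nuclei."""
    thr = thresholds or QCThresholds()
    meta = nm.nucleus_meta
    if modality == "rna":
        keep = (
            (meta["total_counts"] >= thr.min_counts)
            & (meta["n_features_detected"] >= thr.min_genes)
            & (meta["mito_fraction"] < thr.max_mito)
        )
    elif modality == "atac":
        frags = meta["total_counts"]
        keep = (frags >= thr.min_fragments) & (frags <= thr.max_fragments)
        if "tss_enrichment" in meta.columns:
            keep &= meta["tss_enrichment"] >= thr.min_tss_enrichment
    else:
        raise ValueError(f"unknown modality {modality!r}")
    keep = keep.to_numpy()
    if not keep.any():
        warnings.warn("QC removed every nucleus")
    out = nm.subset_nuclei(keep)
    detected = np.asarray((out.counts > 0).sum(axis=0)).ravel()
    feature_keep = detected >= thr.min_nuclei_per_feature
    if not feature_keep.all():
        logger.info(
            "QC removed %d features detected in < %d nuclei",
            int((~feature_keep).sum()), thr.min_nuclei_per_feature,
        )
        out = out.subset_features(feature_keep)
    return out


def aggregate_pseudobulk(
    nm: NucleusMatrix,
    group_by: tuple[str, ...] = ("donor_id", "cell_type"),
) -> PseudobulkAssay:
    """Sum nucleus counts within each group into pseudobulk samples.

    ``group_by = ("donor_id", "cell_type")`` yields the per-cell-type
    replicates used in differential testing; ``("donor_id",)`` the full
    pseudobulk used for covariate selection. Groups with zero nuclei are
    never emitted and totals are conserved exactly (integer sums).
    """
    meta = nm.nucleus_meta
    for col in group_by:
        if col not in meta.columns:
            raise ValueError(f"group_by column {col!r} missing from nucleus metadata")
    keys = meta[list(group_by)].astype(str).agg("|".join, axis=1)
    order = sorted(keys.unique())
    key_to_idx = {k: i for i, k in enumerate(order)}
    row_idx = keys.map(key_to_idx).to_numpy()
    # indicator matrix (groups x nuclei) @ counts = grouped sums
    indicator = sp.csr_matrix(
        (np.ones(len(keys), dtype=np.int64), (row_idx, np.arange(len(keys)))),
        shape=(len(order), len(keys)),
    )
    summed = np.asarray((indicator @ nm.counts).todense())
    sample_meta_rows = []
    for k in order:
        grp = meta.loc[keys == k]
        sample_meta_rows.append(
            {
                "donor_id": grp["donor_id"].iloc[0],
                "cell_type": grp["cell_type"].iloc[0] if "cell_type" in group_by else "all",
                "n_cells": int(len(grp)),
            }
        )
    return PseudobulkAssay(
        values=pd.DataFrame(summed.T, index=nm.feature_ids, columns=order),
        sample_meta=pd.DataFrame(sample_meta_rows, index=order),
        modality="rna_counts",
    )


def compute_gene_scores(
    peak_counts: PseudobulkAssay,
    peaks: PeakSet,
    genes: GeneAnnotation,
    window: int = 100_000,
    decay: float = 5_000.0,
) -> PseudobulkAssay:
    """Distance-weighted gene-activity scores from peak accessibility.

    ``score(g, s) = sum over peaks p within `window` bp of gene g of
    exp(-d(p, g) / decay) * count(p, s)`` where d is 0 for peaks overlapping
    the gene body and otherwise the base-pair gap to the nearest gene-body
    edge. The window is symmetric (100 kb up- and downstream); strand is
    ignored for the distance. Genes with no in-window peak get score 0 and
    are listed in the returned assay's ``sample_meta.attrs`` flag.
    """
    peak_tab = peaks.table.loc[peak_counts.feature_ids]
    gene_tab = genes.table
    n_genes, n_peaks = len(gene_tab), len(peak_tab)
    weights = sp.lil_matrix((n_genes, n_peaks))
    for chrom in gene_tab["chrom"].unique():
        g_mask = (gene_tab["chrom"] == chrom).to_numpy()
        p_mask = (peak_tab["chrom"] == chrom).to_numpy()
        if not p_mask.any():
            continue
        gs = gene_tab.loc[g_mask, "start"].to_numpy()[:, None]
        ge = gene_tab.loc[g_mask, "end"].to_numpy()[:, None]
        ps = peak_tab.loc[p_mask, "start"].to_numpy()[None, :]
        pe = peak_tab.loc[p_mask, "end"].to_numpy()[None, :]
        dist = np.maximum(np.maximum(gs - pe, ps - ge), 0)
        w = np.where(dist <= window, np.exp(-dist / decay), 0.0)
        gi = np.flatnonzero(g_mask)
        pi = np.flatnonzero(p_mask)
        weights[np.ix_(gi, pi)] = w
    weights = weights.tocsr()
    scores = weights @ peak_counts.values.to_numpy()
    values = pd.DataFrame(scores, index=list(gene_tab.index), columns=list(peak_counts.values.columns))
    no_peak = values.index[np.asarray(weights.sum(axis=1)).ravel() == 0].tolist()
    if no_peak:
        logger.info("%d genes have no peak within %d bp; scores set to 0", len(no_peak), window)
    out = PseudobulkAssay(
        values=values,
        sample_meta=peak_counts.sample_meta.copy(),
        modality="atac_genescore",
        normalized=False,
    )
    out.values.attrs["genes_without_peaks"] = no_peak
    return out


def normalize_gene_scores(pb: PseudobulkAssay) -> PseudobulkAssay:
    """Divide each sample's gene scores by its number of aggregated cells."""
    if pb.modality != "atac_genescore":
        raise ValueError("cell-count normalization applies to gene scores only")
    if pb.normalized:
        raise ValueError("gene scores are already cell-count normalized")
    n_cells = pb.sample_meta["n_cells"].to_numpy(dtype=float)
    if (n_cells <= 0).any():
        raise ValueError("n_cells must be positive for normalization")
    values = pb.values / n_cells[None, :]
    return replace(pb, values=values, normalized=True)


def filter_features(
    pb: PseudobulkAssay,
    min_value: float,
    min_fraction: float,
) -> PseudobulkAssay:
    """Keep features passing a value threshold in enough samples.

    A feature is kept when the number of samples with value >= ``min_value``
    (counts) or strictly > ``min_value`` (gene scores, "above") reaches
    ``ceil(min_fraction * n_samples)``. Decisions are feature-wise, so the
    filter is order-independent and idempotent.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    vals = pb.values.to_numpy()
    if pb.modality == "rna_counts":
        passing = (vals >= min_value).sum(axis=1)
    else:
        passing = (vals > min_value).sum(axis=1)
    need = int(np.ceil(min_fraction * pb.n_samples))
    keep = passing >= need
    return replace(pb, values=pb.values.loc[keep])
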