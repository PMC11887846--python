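"""Readers and writers for every on-disk format the pipeline touches.

Counts travel as Matrix Market (.mtx) with TSV sidecars for nucleus metadata
and feature ids; peaks as BED; gene annotation as a 5-column TSV
(gene_id, chrom, start, end, strand; GFF-style 1-based input is converted to
0-based half-open on read when ``one_based=True``); gene sets as GMT; the
motif matrix, cohort table and PRS table as TSV. Outputs are TSV (fixed
float precision, deterministic row order) plus GraphML for networks.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    GeneAnnotation,
    GeneSetCollection,
    MotifAnnotation,
    NucleusMatrix,
    PeakSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

COHORT_COLUMNS = [
    "donor_id",
    "disease_status",
    "diagnosis",
    "sex",
    "age",
    "brain_pH",
    "pmi",
    "rin",
    "lib_batch",
]


# ---------------------------------------------------------------------------
# readers


def read_nucleus_matrix(
    mtx_path: str | Path,
    nucleus_meta_path: str | Path,
    feature_path: str | Path,
) -> NucleusMatrix:
    """Read an MTX count matrix (nuclei x features) with its TSV sidecars."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    meta = pd.read_csv(nucleus_meta_path, sep="\t", dtype={"donor_id": str, "cell_type": str})
    features = pd.read_csv(feature_path, sep="\t")
    if "feature_id" not in features.columns:
        raise ValidationError(f"{feature_path}: expected a 'feature_id' column")
    if len(meta) != counts.shape[0]:
        raise ValidationError(
            f"{nucleus_meta_path}: {len(meta)} metadata rows for a matrix with "
            f"{counts.shape[0]} nuclei (first mismatching row: {min(len(meta), counts.shape[0])})"
        )
    if len(features) != counts.shape[1]:
        raise ValidationError(
            f"{feature_path}: {len(features)} features for a matrix with "
            f"{counts.shape[1]} columns"
        )
    return NucleusMatrix(counts=counts, nucleus_meta=meta, feature_ids=list(features["feature_id"]))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Donor metadata table; categorical fields stay strings, RIN may be NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"donor_id": str, "lib_batch": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: cohort table lacks columns {missing}")
    if df["donor_id"].duplicated().any():
        dup = df["donor_id"][df["donor_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate donor_id {dup!r}")
    return df.sort_values("donor_id").reset_index(drop=True)


def read_prs(path: str | Path) -> pd.DataFrame:
    """Per-donor PRS table: donor_id column plus one column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={"donor_id": str})
    if "donor_id" not in df.columns:
        raise ValidationError(f"{path}: PRS table needs a donor_id column")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: PRS table has no trait columns")
    return df.sort_values("donor_id").reset_index(drop=True)


def read_bed_peaks(path: str | Path) -> PeakSet:
    """BED file of peaks; the 4th column (name) is used as peak_id when present."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{i}: BED line has fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) >= 4 else f"peak_{i}"
            rows.append((name, chrom, start, end))
    table = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"]).set_index("peak_id")
    return PeakSet(table=table.sort_values(["chrom", "start"]))


def read_gene_annotation(path: str | Path, one_based: bool = False) -> GeneAnnotation:
    """TSV gene annotation: gene_id, chrom, start, end, strand.

    ``one_based=True`` converts GFF-style 1-based inclusive coordinates to
    0-based half-open (start - 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: gene annotation needs columns {sorted(required)}")
    if one_based:
        df["start"] = df["start"] - 1
    return GeneAnnotation(table=df.set_index("gene_id").sort_values(["chrom", "start"]))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT gene sets: set_id <tab> description <tab> member..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{i}: GMT line has fewer than 3 fields")
            set_id, description, *members = parts
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(f"{path}:{i}: duplicate members in set {set_id!r} deduplicated")
            if not unique:
                raise ValidationError(f"{path}:{i}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise ValidationError(f"{path}:{i}: duplicate set id {set_id!r}")
            sets[set_id] = (description, unique)
    return GeneSetCollection(sets=sets)


def read_motif_annotation(path: str | Path, peaks: PeakSet | None = None) -> MotifAnnotation:
    """TSV binary matrix with a peak_id column and one 0/1 column per motif."""
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str}).set_index("peak_id")
    annot = MotifAnnotation(table=df.sort_index())
    if peaks is not None:
        unknown = set(annot.table.index) - set(peaks.peak_ids)
        if unknown:
            raise ValidationError(
                f"{path}: {len(unknown)} motif-annotated peaks absent from the peak "
                f"set (e.g. {sorted(unknown)[0]!r})"
            )
    return annot


def read_inputs(paths: Mapping[str, str | Path]) -> dict:
    """Read and cross-validate the full input bundle.

    ``paths`` maps logical names (``counts_mtx``, ``nucleus_meta``, ``features``,
    ``cohort``, ``prs``, ``genes``, ``peaks``, ``gene_sets``, ``motifs``) to
    files; optional entries may be omitted. Donor ids in nucleus metadata and
    the PRS table must exist in the cohort table.
    """
    bundle: dict = {}
    bundle["cohort"] = read_cohort(paths["cohort"])
    donors = set(bundle["cohort"]["donor_id"])
    if "counts_mtx" in paths:
        nm = read_nucleus_matrix(paths["counts_mtx"], paths["nucleus_meta"], paths["features"])
        unknown = set(nm.nucleus_meta["donor_id"]) - donors
        if unknown:
            raise ValidationError(
                f"nucleus metadata references donors absent from the cohort table: "
                f"{sorted(unknown)[:5]}"
            )
        bundle["nuclei"] = nm
    if "prs" in paths:
        prs = read_prs(paths["prs"])
        unknown = set(prs["donor_id"]) - donors
        if unknown:
            raise ValidationError(f"PRS table references unknown donors: {sorted(unknown)[:5]}")
        bundle["prs"] = prs
    if "genes" in paths:
        bundle["genes"] = read_gene_annotation(paths["genes"])
    if "peaks" in paths:
        bundle["peaks"] = read_bed_peaks(paths["peaks"])
    if "gene_sets" in paths:
        bundle["gene_sets"] = read_gmt(paths["gene_sets"])
    if "motifs" in paths:
        bundle["motifs"] = read_motif_annotation(paths["motifs"], bundle.get("peaks"))
    return bundle


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_nucleus_matrix(nm: NucleusMatrix, out_dir: str | Path, prefix: str = "counts") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / f"{prefix}.mtx"), sp.coo_matrix(nm.counts))
    _write_tsv(nm.nucleus_meta, out / f"{prefix}_nuclei.tsv")
    _write_tsv(pd.DataFrame({"feature_id": nm.feature_ids}), out / f"{prefix}_features.tsv")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(cohort.sort_values("donor_id"), Path(path))


def write_bed_peaks(peaks: PeakSet, path: str | Path) -> None:
    df = peaks.table.sort_values(["chrom", "start"]).reset_index()
    df[["chrom", "start", "end", "peak_id"]].to_csv(path, sep="\t", index=False, header=False)


def write_gene_annotation(genes: GeneAnnotation, path: str | Path) -> None:
    _write_tsv(genes.table.sort_values(["chrom", "start"]).reset_index(), Path(path))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets.sets):
            description, members = sets.sets[set_id]
            fh.write("\t".join([set_id, description, *members]) + "\n")


def write_motif_annotation(annot: MotifAnnotation, path: str | Path) -> None:
    _write_tsv(annot.table.sort_index().reset_index(), Path(path))


def write_pseudobulk(pb, out_dir: str | Path, prefix: str) -> None:
    """Write a PseudobulkAssay as a value TSV plus a sample-metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pb.values.rename_axis("feature_id").to_csv(
        out / f"{prefix}.tsv", sep="\t", float_format="%.10g"
    )
    meta = pb.sample_meta.rename_axis("sample_id").reset_index()
    meta["modality"] = pb.modality
    meta["normalized"] = pb.normalized
    _write_tsv(meta, out / f"{prefix}_samples.tsv")


def read_pseudobulk(values_path: str | Path, samples_path: str | Path):
    """Read a PseudobulkAssay written by :func:`write_pseudobulk`."""
    from .containers import PseudobulkAssay

    values = pd.read_csv(values_path, sep="\t", index_col="feature_id").rename_axis(None)
    meta = (
        pd.read_csv(samples_path, sep="\t", dtype={"donor_id": str})
        .set_index("sample_id")
        .rename_axis(None)
    )
    modality = meta["modality"].iloc[0]
    normalized = bool(meta["normalized"].iloc[0])
    meta = meta.drop(columns=["modality", "normalized"])
    if list(values.columns) != list(meta.index):
        raise ValidationError(
            f"{samples_path}: sample ids do not match the columns of {values_path}"
        )
    if modality == "rna_counts":
        values = values.round().astype(np.int64)
    return PseudobulkAssay(values=values, sample_meta=meta, modality=modality, normalized=normalized)


def write_differential_results(results: pd.DataFrame, path: str | Path) -> None:
    """Differential testing table; sorted for byte-stable reruns."""
    cols = [
        "gene_id", "log2FC", "SE", "wald_statistic", "p_value", "fdr",
        "n_samples_used", "cell_type", "modality", "contrast",
    ]
    out = results.reindex(columns=cols)
    out = out.sort_values(["contrast", "modality", "cell_type", "gene_id"])
    _write_tsv(out, Path(path))


def write_enrichment_results(results: pd.DataFrame, path: str | Path) -> None:
    sort_cols = [c for c in ("cell_type", "direction", "set_id") if c in results.columns]
    _write_tsv(results.sort_values(sort_cols) if sort_cols else results, Path(path))


def write_network(graph: nx.Graph, out_dir: str | Path, prefix: str = "network") -> None:
    """Write a correlation network as an edge-list TSV and GraphML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "source": u,
            "target": v,
            "rho": d["rho"],
            "p_value": d["p_value"],
            "sign": d["sign"],
            "weight": d["weight"],
        }
        for u, v, d in graph.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p_value", "sign", "weight"])
    _write_tsv(edges.sort_values(["source", "target"]), out / f"{prefix}_edges.tsv")
    nx.write_graphml(graph, out / f"{prefix}.graphml")


def write_outputs(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write a results bundle; returns the files written (sorted).

    Recognized keys: ``differential`` (DataFrame), ``enrichment`` (DataFrame),
    ``network`` (networkx Graph), ``risk_groups`` (DataFrame),
    ``covariate_report`` (DataFrame).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "differential" in results:
        p = out / "differential_results.tsv"
        write_differential_results(results["differential"], p)
        written.append(p)
    if "enrichment" in results:
        p = out / "enrichment_results.tsv"
        write_enrichment_results(results["enrichment"], p)
        written.append(p)
    if "network" in results:
        write_network(results["network"], out)
        written += [out / "network_edges.tsv", out / "network.graphml"]
    if "risk_groups" in results:
        p = out / "risk_groups.tsv"
        _write_tsv(results["risk_groups"].sort_values("donor_id"), p)
        written.append(p)
    if "covariate_report" in results:
        p = out / "covariate_report.tsv"
        _write_tsv(results["covariate_report"], p)
        written.append(p)
    return sorted(written)
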