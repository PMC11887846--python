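"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three representations:

* :class:`NucleusMatrix` — per-nucleus counts with nucleus-level metadata,
  the entry point for QC and pseudobulk aggregation;
* :class:`PseudobulkAssay` — feature x sample matrix per modality
  (summed RNA counts or chromatin-accessibility gene scores), the unit of
  differential testing;
* small annotation tables (genes, peaks, gene sets, motifs) kept as plain
  :class:`pandas.DataFrame` / dict structures.

All genomic coordinates are BED-style 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NucleusMatrix",
    "PseudobulkAssay",
    "GeneAnnotation",
    "PeakSet",
    "GeneSetCollection",
    "MotifAnnotation",
    "ValidationError",
]

NUCLEUS_META_COLUMNS = (
    "nucleus_id",
    "donor_id",
    "cell_type",
    "total_counts",
    "n_features_detected",
    "mito_fraction",
)


class ValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass
class NucleusMatrix:
    """Sparse nuclei x features count matrix plus per-nucleus metadata.

    ``counts`` holds non-negative integers (CSR); ``nucleus_meta`` has one row
    per matrix row with at least the columns in :data:`NUCLEUS_META_COLUMNS`;
    ``feature_ids`` orders the columns.
    """

    counts: sp.csr_matrix
    nucleus_meta: pd.DataFrame
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.nucleus_meta):
            raise ValidationError(
                f"nucleus metadata has {len(self.nucleus_meta)} rows but the "
                f"count matrix has {self.counts.shape[0]} nuclei"
            )
        if self.counts.shape[1] != len(self.feature_ids):
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for a matrix with "
                f"{self.counts.shape[1]} columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative values in nucleus count matrix")
        missing = [c for c in NUCLEUS_META_COLUMNS if c not in self.nucleus_meta.columns]
        if missing:
            raise ValidationError(f"nucleus metadata lacks columns: {missing}")
        self.nucleus_meta = self.nucleus_meta.reset_index(drop=True)

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_nuclei(self, mask: np.ndarray) -> "NucleusMatrix":
        mask = np.asarray(mask)
        return NucleusMatrix(
            counts=self.counts[mask],
            nucleus_meta=self.nucleus_meta.loc[mask].reset_index(drop=True),
            feature_ids=list(self.feature_ids),
        )

    def subset_features(self, mask: np.ndarray) -> "NucleusMatrix":
        mask = np.asarray(mask)
        kept = [f for f, m in zip(self.feature_ids, mask) if m]
        return NucleusMatrix(
            counts=self.counts[:, mask],
            nucleus_meta=self.nucleus_meta.copy(),
            feature_ids=kept,
        )


@dataclass
class PseudobulkAssay:
    """Feature x sample matrix for one modality.

    ``values`` is a DataFrame (rows = features, columns = sample ids).
    ``sample_meta`` is indexed by sample id with columns ``donor_id``,
    ``cell_type`` and ``n_cells``. ``modality`` is ``"rna_counts"`` (integer
    sums of nucleus counts) or ``"atac_genescore"`` (non-negative reals).
    ``normalized`` records whether gene scores were already divided by the
    number of aggregated cells; double normalization is refused downstream.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    modality: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("rna_counts", "atac_genescore"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValidationError("sample_meta index does not match value columns")
        for col in ("donor_id", "cell_type", "n_cells"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta lacks column {col!r}")
        if (self.sample_meta["n_cells"] < 1).any():
            raise ValidationError("every pseudobulk sample needs n_cells >= 1")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative pseudobulk values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_samples(self, sample_ids: list[str]) -> "PseudobulkAssay":
        return replace(
            self,
            values=self.values.loc[:, sample_ids],
            sample_meta=self.sample_meta.loc[sample_ids],
        )

    def subset_features(self, feature_ids: list[str]) -> "PseudobulkAssay":
        return replace(self, values=self.values.loc[feature_ids])


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValidationError(f"{what} {bad!r} has start >= end")
    return df


@dataclass
class GeneAnnotation:
    """Gene bodies: gene_id, chrom, start, end, strand (0-based half-open)."""

    table: pd.DataFrame  # indexed by gene_id

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"gene annotation needs columns {sorted(required)}")
        if not self.table.index.is_unique:
            raise ValidationError("duplicate gene ids in annotation")
        self.table.index.name = "gene_id"
        bad_strand = set(self.table["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"invalid strand values: {sorted(bad_strand)}")
        _check_intervals(self.table, "gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def tss(self) -> pd.Series:
        """Transcription start site: start for + genes, end-1 for - genes."""
        t = self.table
        return pd.Series(
            np.where(t["strand"] == "+", t["start"], t["end"] - 1),
            index=t.index,
            name="tss",
        )


@dataclass
class PeakSet:
    """Accessibility peaks: peak_id, chrom, start, end (0-based half-open)."""

    table: pd.DataFrame  # indexed by peak_id

    def __post_init__(self) -> None:
        if not {"chrom", "start", "end"}.issubset(self.table.columns):
            raise ValidationError("peak set needs columns chrom, start, end")
        self.table.index.name = "peak_id"
        if not self.table.index.is_unique:
            raise ValidationError("duplicate peak ids")
        _check_intervals(self.table, "peak")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.table.index)

    def widths(self) -> pd.Series:
        return self.table["end"] - self.table["start"]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway stand-ins): set_id -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def as_dict(self) -> Mapping[str, list[str]]:
        return {k: v[1] for k, v in self.sets.items()}


@dataclass
class MotifAnnotation:
    """Binary peaks x motifs presence matrix."""

    table: pd.DataFrame  # index = peak_id, columns = motif ids, values 0/1

    def __post_init__(self) -> None:
        self.table.index.name = "peak_id"
        vals = self.table.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("motif annotation must be binary")
        if not self.table.index.is_unique:
            raise ValidationError("duplicate peak ids in motif annotation")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.table.columns)
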