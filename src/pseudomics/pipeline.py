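"""End-to-end pipeline: simulate or load inputs, then run every stage.

Stage order mirrors the analysis it implements: QC/aggregation (or direct
pseudobulk simulation) -> covariate screening on the full pseudobulk ->
per-cell-type differential testing for the diagnosis and/or risk contrasts
-> pathway and motif enrichment -> multi-omic correlation network ->
cell-type proportion comparison. A run is fully determined by its config
and seed; rerunning writes byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .containers import PseudobulkAssay
from .covariates import (
    associate_covariates_with_pcs,
    pca_scores,
    transform_counts,
)
from .differential import Contrast, DifferentialConfig, run_differential
from .downstream import (
    compare_proportions,
    cross_study_fc_correlation,
    motif_enrichment,
    pathway_enrichment,
    spearman_network,
)
from .pseudobulk import filter_features, normalize_gene_scores
from .risk import define_risk_groups
from . import synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SimulateConfig", "validate_config", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "out_dir", "contrasts", "n_extreme", "inputs", "simulate",
    "differential", "enrichment_top_n", "network_p_threshold",
    "covariate_alpha", "full_pseudobulk_min_count", "full_pseudobulk_min_fraction",
    "n_motif_genes",
}


@dataclass
class SimulateConfig:
    """Synthetic-input block: cohort size, assay dimensions, planted truth."""

    n_donors: int = 90
    cell_types: list[str] = field(default_factory=lambda: ["Exc_L2-3", "Oligodendrocyte"])
    n_genes: int = 1000
    n_peaks: int = 3000
    n_motifs: int = 50
    n_sets: int = 30
    case_fraction: float = synthetic.CASE_FRACTION
    liability_correlation: float = 0.3
    truth: synthetic.TruthSpec = field(default_factory=synthetic.TruthSpec)


@dataclass
class PipelineConfig:
    """Everything a run needs; every threshold carries the study default."""

    seed: int = 0
    out_dir: str | None = None
    contrasts: list[dict] = field(
        default_factory=lambda: [{"kind": "diagnosis"}, {"kind": "risk", "trait": "schizophrenia"}]
    )
    n_extreme: int = 20
    inputs: dict[str, str] | None = None
    simulate: SimulateConfig | None = None
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    enrichment_top_n: int = 250
    network_p_threshold: float = 0.05
    covariate_alpha: float = 0.05
    full_pseudobulk_min_count: float = 10.0
    full_pseudobulk_min_fraction: float = 0.9  # covariate screen: 10 counts in 90%
    n_motif_genes: int = 5

    def config_hash(self) -> str:
        # out_dir is location metadata, not analysis configuration
        payload = {k: v for k, v in _serialize(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    return obj


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Normalize a raw mapping into a PipelineConfig; all errors at once."""
    if isinstance(raw, PipelineConfig):
        raw_dict = _serialize(raw)
    else:
        raw_dict = dict(raw)
    errors = []
    unknown = set(raw_dict) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    diff_kwargs = raw_dict.pop("differential", {}) or {}
    sim_kwargs = raw_dict.pop("simulate", None)
    cfg = None
    try:
        truth_kwargs = {}
        if sim_kwargs is not None:
            sim_kwargs = dict(sim_kwargs)
            truth_kwargs = sim_kwargs.pop("truth", {}) or {}
        cfg = PipelineConfig(
            **{k: v for k, v in raw_dict.items() if k in _KNOWN_KEYS},
            differential=DifferentialConfig(**diff_kwargs),
            simulate=(
                SimulateConfig(**sim_kwargs, truth=synthetic.TruthSpec(**truth_kwargs))
                if sim_kwargs is not None
                else None
            ),
        )
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
    if cfg is not None:
        d = cfg.differential
        for name, frac in (
            ("min_count_fraction", d.min_count_fraction),
            ("min_score_fraction", d.min_score_fraction),
            ("full_pseudobulk_min_fraction", cfg.full_pseudobulk_min_fraction),
        ):
            if not 0 < frac <= 1:
                errors.append(f"{name} must lie in (0, 1], got {frac}")
        if not 0 <= d.fdr_threshold <= 1:
            errors.append(f"fdr_threshold must lie in [0, 1], got {d.fdr_threshold}")
        if cfg.inputs is None and cfg.simulate is None:
            cfg.simulate = SimulateConfig()
        for c in cfg.contrasts:
            if c.get("kind") == "risk" and not c.get("trait"):
                errors.append("risk contrast needs a 'trait'")
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    return cfg


def _full_pseudobulk(expr: dict[str, PseudobulkAssay]) -> PseudobulkAssay:
    """Sum per-cell-type pseudobulks into one donor-level matrix."""
    assays = list(expr.values())
    donors = sorted(assays[0].sample_meta["donor_id"].unique())
    genes = assays[0].feature_ids
    total = pd.DataFrame(0.0, index=genes, columns=donors)
    n_cells = pd.Series(0, index=donors, dtype=int)
    for a in assays:
        by_donor = a.values.T.groupby(a.sample_meta["donor_id"].to_numpy()).sum().T
        total.loc[:, by_donor.columns] += by_donor
        n_cells = n_cells.add(
            a.sample_meta.groupby("donor_id")["n_cells"].sum(), fill_value=0
        ).astype(int)
    return PseudobulkAssay(
        values=total,
        sample_meta=pd.DataFrame(
            {"donor_id": donors, "cell_type": "all", "n_cells": n_cells.loc[donors].to_numpy()},
            index=donors,
        ),
        modality="rna_counts",
    )


def _simulate_inputs(cfg: PipelineConfig) -> dict:
    sim = cfg.simulate
    rng = np.random.default_rng(cfg.seed)
    sub = lambda: int(rng.integers(2**31 - 1))  # noqa: E731 - stage sub-seeds
    cohort = synthetic.generate_cohort(sim.n_donors, sim.case_fraction, seed=sub())
    traits = sorted({c["trait"] for c in cfg.contrasts if c.get("kind") == "risk"})
    if not traits:
        traits = [sim.truth.risk_trait]
    prs = None
    for t in traits:
        prs = synthetic.generate_prs(cohort, t, sim.liability_correlation, seed=sub(), prs=prs)
    genes, peaks, motifs, gene_sets = synthetic.generate_annotations(
        sim.n_genes, sim.n_peaks, sim.n_motifs, sim.n_sets, seed=sub()
    )
    truth_spec = dataclasses.replace(sim.truth, risk_trait=traits[0])
    compositions = synthetic.generate_cell_compositions(cohort, sim.cell_types, seed=sub())
    expr, truth_expr = synthetic.generate_expression_counts(
        cohort, sim.cell_types, sim.n_genes, truth_spec, seed=sub(), prs=prs,
        n_cells=compositions["rna"],
    )
    scores, truth_atac = synthetic.generate_gene_scores(
        cohort, sim.cell_types, sim.n_genes, truth_spec, seed=sub(), prs=prs,
        n_cells=compositions["atac"],
    )
    return {
        "cohort": cohort, "prs": prs, "genes": genes, "peaks": peaks,
        "motifs": motifs, "gene_sets": gene_sets, "expression": expr,
        "gene_scores": scores, "truth_expression": truth_expr,
        "truth_accessibility": truth_atac,
    }


def _screen_covariates(cfg: PipelineConfig, expr: dict, cohort: pd.DataFrame):
    full = _full_pseudobulk(expr)
    full = filter_features(full, cfg.full_pseudobulk_min_count, cfg.full_pseudobulk_min_fraction)
    if full.n_features < 2:
        logger.warning("full pseudobulk too sparse for covariate screening")
        return None
    transformed, _ = transform_counts(full.values)
    scores, _ = pca_scores(transformed.to_numpy().T, n_pcs=10)
    cohort_aligned = cohort.set_index("donor_id").loc[full.sample_meta["donor_id"]].reset_index()
    report = associate_covariates_with_pcs(scores, cohort_aligned, alpha=cfg.covariate_alpha)
    logger.info("covariate screen selected: %s", report.selected)
    return report


def run_pipeline(config: dict | PipelineConfig) -> dict:
    """Execute every stage; returns the results bundle (and writes out_dir).

    The bundle maps stage names to their results: ``cohort``, ``prs``,
    ``covariate_report``, ``risk_groups`` (per trait), ``differential``
    (one tidy table), ``pathway_enrichment``, ``motif_enrichment``,
    ``network``, ``proportions`` and, for simulated inputs, the recorded
    truth objects.
    """
    cfg = validate_config(config)
    if cfg.inputs is not None:
        raise NotImplementedError(
            "file-based pipeline inputs: read them with io_formats.read_inputs "
            "and pass assays to the stage functions directly"
        )
    data = _simulate_inputs(cfg)
    cohort, prs = data["cohort"], data["prs"]
    results: dict = {"cohort": cohort, "prs": prs, "config": cfg}
    results["truth_expression"] = data["truth_expression"]
    results["truth_accessibility"] = data["truth_accessibility"]

    results["covariate_report"] = _screen_covariates(cfg, data["expression"], cohort)

    risk_traits = sorted({c["trait"] for c in cfg.contrasts if c.get("kind") == "risk"})
    results["risk_groups"] = {
        t: define_risk_groups(cohort, prs, t, n_extreme=cfg.n_extreme) for t in risk_traits
    }

    diff_frames = []
    for spec in cfg.contrasts:
        if spec["kind"] == "diagnosis":
            contrast = Contrast(kind="diagnosis")
        else:
            contrast = Contrast(
                kind="risk", trait=spec["trait"],
                assignment=results["risk_groups"][spec["trait"]].assignment_frame(),
            )
        for ct in sorted(data["expression"]):
            res = run_differential(data["expression"][ct], cohort, contrast, cfg.differential)
            if res is not None:
                diff_frames.append(res)
        for ct in sorted(data["gene_scores"]):
            res = run_differential(data["gene_scores"][ct], cohort, contrast, cfg.differential)
            if res is not None:
                diff_frames.append(res)
    differential = (
        pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame()
    )
    results["differential"] = differential

    if len(differential):
        rna = differential[differential["modality"] == "rna_counts"]
        results["pathway_enrichment"] = pathway_enrichment(
            rna, data["gene_sets"], top_n=cfg.enrichment_top_n
        )
        sig = differential[
            differential["significant"].fillna(False) & (differential["modality"] == "rna_counts")
        ]
        top_genes = (
            sig.sort_values(["fdr", "gene_id"]).drop_duplicates("gene_id")["gene_id"]
            .head(cfg.n_motif_genes)
            .tolist()
        )
        results["motif_enrichment"] = {
            g: motif_enrichment(g, data["genes"], data["peaks"], data["motifs"])
            for g in top_genes
        }
        results["network"] = _risk_network(cfg, results, data)

    results["proportions"] = _compare_modality_proportions(data)
    results["cross_contrast_correlation"] = _cross_contrast(differential)

    if cfg.out_dir:
        _write_bundle(cfg, results, data)
    return results


def _risk_network(cfg: PipelineConfig, results: dict, data: dict):
    """Network over top risk genes (expression + accessibility) + PRS + status."""
    differential = results["differential"]
    risk_traits = sorted(results["risk_groups"])
    if not risk_traits:
        return None
    trait = risk_traits[0]
    label = f"risk:{trait}"
    risk_res = differential[differential["contrast"] == label]
    if not len(risk_res):
        return None
    sig = risk_res[risk_res["significant"].fillna(False)]
    genes = (
        sig.sort_values(["fdr", "gene_id"]).drop_duplicates("gene_id")["gene_id"]
        .head(10).tolist()
    )
    if not genes:
        return None
    assignment = results["risk_groups"][trait].assignment_frame()
    donors = sorted(assignment["donor_id"])
    cohort = results["cohort"].set_index("donor_id").loc[donors]
    ct = sorted(data["expression"])[0]
    expr = data["expression"][ct]
    score = normalize_gene_scores(data["gene_scores"][ct])
    cols, meta_rows = {}, []
    expr_by_donor = expr.values.T.set_axis(expr.sample_meta["donor_id"], axis=0)
    score_by_donor = score.values.T.set_axis(score.sample_meta["donor_id"], axis=0)
    for g in genes:
        if g in expr.values.index:
            cols[f"expr:{g}"] = np.log2(expr_by_donor.loc[donors, g].to_numpy(float) + 1)
            meta_rows.append({"feature": f"expr:{g}", "modality": "expression", "cell_type": ct})
        if g in score.values.index:
            cols[f"acc:{g}"] = np.log2(score_by_donor.loc[donors, g].to_numpy(float) + 1)
            meta_rows.append({"feature": f"acc:{g}", "modality": "accessibility", "cell_type": ct})
    for t in risk_traits:
        cols[f"prs:{t}"] = results["prs"].set_index("donor_id").loc[donors, t].to_numpy()
        meta_rows.append({"feature": f"prs:{t}", "modality": "prs", "cell_type": "n/a"})
    cols["status"] = (cohort["disease_status"] == "case").to_numpy(float)
    meta_rows.append({"feature": "status", "modality": "status", "cell_type": "n/a"})
    features = pd.DataFrame(cols, index=donors)
    node_meta = pd.DataFrame(meta_rows).set_index("feature")
    covs = np.column_stack(
        [
            (cohort["sex"] == "M").to_numpy(float),
            cohort["age"].to_numpy(float),
            cohort["rin"].fillna(cohort["rin"].median()).to_numpy(float),
            cohort["pmi"].to_numpy(float),
            cohort["brain_pH"].to_numpy(float),
        ]
    )
    return spearman_network(features, node_meta, covs, p_threshold=cfg.network_p_threshold)


def _compare_modality_proportions(data: dict):
    """Cell-type proportions per donor, RNA vs ATAC, from aggregated n_cells."""
    def props(assays: dict[str, PseudobulkAssay]) -> pd.DataFrame:
        counts = pd.DataFrame(
            {ct: a.sample_meta.set_index("donor_id")["n_cells"] for ct, a in assays.items()}
        ).fillna(0)
        return counts.div(counts.sum(axis=1), axis=0)

    pa, pb = props(data["expression"]), props(data["gene_scores"])
    if pa.shape[1] < 2:
        return None
    table, donor_corr = compare_proportions(pa, pb)
    return {"tests": table, "donor_correlations": donor_corr,
            "median_donor_correlation": float(donor_corr.median())}


def _cross_contrast(differential: pd.DataFrame):
    """Effect-size correlation between the diagnosis and risk DE tables."""
    if not len(differential):
        return None
    rna = differential[differential["modality"] == "rna_counts"]
    a = rna[rna["contrast"] == "diagnosis"]
    risk_labels = sorted(set(rna["contrast"]) - {"diagnosis"})
    if not len(a) or not risk_labels:
        return None
    b = rna[rna["contrast"] == risk_labels[0]]
    corr, shared = cross_study_fc_correlation(a, b)
    return {"correlation": corr, "shared_genes": shared}


def _write_bundle(cfg: PipelineConfig, results: dict, data: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serial = {k: v for k, v in _serialize(cfg).items() if k != "out_dir"}
    (out / "config.yaml").write_text(yaml.safe_dump(serial, sort_keys=True))
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": cfg.config_hash(), "seed": cfg.seed}, indent=1)
    )
    payload: dict = {}
    if len(results["differential"]):
        payload["differential"] = results["differential"]
    if results.get("pathway_enrichment") is not None and len(results.get("pathway_enrichment", [])):
        payload["enrichment"] = results["pathway_enrichment"]
    if results.get("network") is not None:
        payload["network"] = results["network"]
    if results.get("risk_groups"):
        frames = []
        for t, rg in sorted(results["risk_groups"].items()):
            frame = rg.table.copy()
            frame.insert(0, "trait", t)
            frames.append(frame)
        payload["risk_groups"] = pd.concat(frames, ignore_index=True)
    if results.get("covariate_report") is not None:
        payload["covariate_report"] = results["covariate_report"].table
    io_formats.write_outputs(payload, out)
    io_formats.write_cohort(results["cohort"], out / "cohort.tsv")
    results["truth_expression"].to_json(out / "truth_expression.json")
    results["truth_accessibility"].to_json(out / "truth_accessibility.json")
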