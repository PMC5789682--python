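"""End-to-end orchestration of the candidate-discovery pipeline.

Stages, in order: MAF filtering of the cohort variant table; fold-change
classification of the two-group FPKM matrix; ortholog cross-referencing
under the direction policy; escalation of the fold-change cutoff
(1.5 -> 2 by default); multi-criteria scoring; knockout-dependence
annotation (when a knockout count matrix is supplied); report assembly
with a per-stage funnel.  Analysis stages are deterministic; the only
randomness in the package lives in :mod:`crossprio.simulate`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .expression import (
    Direction,
    de_test_adjusted,
    escalate_cutoff,
    fold_change_de,
)
from .prioritize import (
    CandidateReport,
    PrioritizationConfig,
    annotate_ko_dependence,
    build_report,
    crossref,
    score_candidates,
)
from .tables_io import (
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
    VariantRecord,
    read_expression_matrix,
    read_gene_set,
    read_ortholog_map,
    read_variant_table,
)
from .variants import filter_vus, tag_insilico

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_objects"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and (optionally) file paths for one pipeline run."""

    variants_path: str | None = None
    fpkm_path: str | None = None
    ko_counts_path: str | None = None
    ortholog_map_path: str | None = None
    known_genes_path: str | None = None
    cell_type_path: str | None = None
    fpkm_ref_group: str = "YB6"
    fpkm_alt_group: str = "YPOS"
    ko_ref_group: str = "XY_WT"
    ko_alt_group: str = "XY_KO"
    maf_cutoff_percent: float = 1.0
    fc_cutoff_initial: float = 1.5
    fc_cutoff_escalated: float = 2.0
    pseudocount: float = 0.1
    direction_policy: str = "under"
    alpha: float = 0.05
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)

    def __post_init__(self) -> None:
        if self.fc_cutoff_escalated < self.fc_cutoff_initial:
            raise ValueError("escalated cutoff must be >= initial cutoff")
        if not self.fc_cutoff_initial > 1:
            raise ValueError("fc_cutoff_initial must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.maf_cutoff_percent > 0:
            raise ValueError("maf_cutoff_percent must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        prio = raw.pop("prioritization", None)
        if prio is not None:
            raw["prioritization"] = PrioritizationConfig(**prio)
        return cls(**raw)


def _read_cell_type(path: str | Path) -> dict[str, bool]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    gene_col, flag_col = df.columns[:2]
    truthy = {"yes", "true", "1", "y"}
    return {
        str(row[gene_col]).upper(): str(row[flag_col]).strip().lower() in truthy
        for _, row in df.iterrows()
    }


def run_pipeline_objects(
    records: list[VariantRecord],
    fpkm: ExpressionMatrix,
    ortholog_map: OrthologMap,
    ko_counts: ExpressionMatrix | None = None,
    known_gene_set: GeneSet | None = None,
    cell_type_annotation: Mapping[str, bool] | None = None,
    config: PipelineConfig | None = None,
) -> CandidateReport:
    """Run the full pipeline on in-memory inputs and return the report.

    Equivalent, stage by stage, to calling the module functions by hand;
    the funnel records each stage's in/out counts.
    """
    cfg = config or PipelineConfig()
    records = tag_insilico(records)
    cohort = filter_vus(records, cfg.maf_cutoff_percent, known_gene_set)
    logger.info("stage=filter_vus in=%d out=%d", cohort.n_input_records, len(cohort.survivors))

    de_initial = fold_change_de(
        fpkm, cfg.fpkm_ref_group, cfg.fpkm_alt_group,
        fc_cutoff=cfg.fc_cutoff_initial, pseudocount=cfg.pseudocount,
    )
    n_de_initial = sum(1 for r in de_initial if r.direction != Direction.UNCHANGED)
    xr_initial = crossref(cohort, de_initial, ortholog_map, cfg.direction_policy)
    logger.info("stage=crossref cutoff=%.2f pool=%d unmapped=%d",
                cfg.fc_cutoff_initial, len(xr_initial.pool), len(xr_initial.unmapped_genes))

    de_escalated = escalate_cutoff(de_initial, cfg.fc_cutoff_escalated)
    xr_escalated = crossref(cohort, de_escalated, ortholog_map, cfg.direction_policy)
    logger.info("stage=escalate cutoff=%.2f pool=%d",
                cfg.fc_cutoff_escalated, len(xr_escalated.pool))

    candidates = score_candidates(
        xr_escalated.pool, cfg.prioritization, cell_type_annotation
    )

    if ko_counts is not None:
        ko_records = de_test_adjusted(
            ko_counts, cfg.ko_ref_group, cfg.ko_alt_group, alpha=cfg.alpha
        )
        candidates = annotate_ko_dependence(candidates, ko_records, ortholog_map, cfg.alpha)

    funnel = {
        "records_in": cohort.n_input_records,
        "records_pass_maf": len(cohort.survivors),
        "records_known_gene": len(cohort.known_gene_records),
        "vus_genes": len(cohort.genes),
        "de_genes_initial": n_de_initial,
        "pool_initial": len(xr_initial.pool),
        "pool_escalated": len(xr_escalated.pool),
        "candidates_scored": len(candidates),
        "unmapped_vus_genes": len(xr_escalated.unmapped_genes),
    }
    parameters = {
        "maf_cutoff_percent": cfg.maf_cutoff_percent,
        "fc_cutoff_initial": cfg.fc_cutoff_initial,
        "fc_cutoff_escalated": cfg.fc_cutoff_escalated,
        "pseudocount": cfg.pseudocount,
        "direction_policy": cfg.direction_policy,
        "alpha": cfg.alpha,
    }
    return build_report(candidates, funnel, parameters)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> CandidateReport:
    """File-based entry point: read the configured inputs, run, optionally write.

    Any stage failure aborts with the stage name and cause.
    """
    for attr in ("variants_path", "fpkm_path", "ortholog_map_path"):
        if getattr(config, attr) is None:
            raise ValueError(f"pipeline config requires {attr}")
    try:
        records = read_variant_table(config.variants_path)
        fpkm = read_expression_matrix(config.fpkm_path, unit="FPKM")
        ortholog_map = read_ortholog_map(config.ortholog_map_path)
        ko_counts = (
            read_expression_matrix(config.ko_counts_path, unit="counts")
            if config.ko_counts_path
            else None
        )
        known = (
            read_gene_set(config.known_genes_path, species="human")
            if config.known_genes_path
            else None
        )
        cell_type = _read_cell_type(config.cell_type_path) if config.cell_type_path else None
    except Exception as exc:
        raise RuntimeError(f"stage=read_inputs failed: {exc}") from exc
    report = run_pipeline_objects(
        records, fpkm, ortholog_map, ko_counts, known, cell_type, config
    )
    if outdir is not None:
        report.write(outdir)
    return report
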