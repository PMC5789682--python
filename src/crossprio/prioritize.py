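"""Cross-species candidate-gene prioritization.

The core of the pipeline: human genes carrying a VUS are intersected,
through an ortholog map, with mouse genes differentially expressed in the
dysgenetic-gonad model; candidates matching the direction policy (by
default only genes *under*-expressed in the affected males) are then
ranked by a weighted multi-criteria priority score and annotated for
dependence on the Sox9 knockout comparison.

The score formalizes a qualitative triage — variant rarity, residue
conservation, cohort recurrence, in-silico pathogenicity, gonadal
cell-type expression, and fold-change magnitude — as a weighted additive
score with each component normalized to [0, 1].  Weights default to equal
(1/6 each) and must sum to 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import DERecord, Direction
from .tables_io import OrthologMap, VariantRecord
from .variants import VusCohort, deleterious_count

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_COMPONENTS",
    "PrioritizationConfig",
    "KoDependence",
    "CandidateGene",
    "CrossrefResult",
    "CandidateReport",
    "crossref",
    "score_candidates",
    "annotate_ko_dependence",
    "build_report",
]

SCORE_COMPONENTS = (
    "rarity",
    "conservation",
    "recurrence",
    "insilico",
    "cell_type",
    "fc_magnitude",
)


@dataclass(frozen=True)
class PrioritizationConfig:
    """Weights and knee points for the multi-criteria priority score.

    ``rarity_full_percent`` is the MAF (percent) at or below which the
    rarity component saturates at 1; it decays linearly to 0 at
    ``vus_cutoff_percent``.  ``fc_saturation`` is the fold change at which
    the magnitude component saturates.  ``recurrence_cap`` is the number
    of distinct carrier patients needed to saturate recurrence.
    """

    weights: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / len(SCORE_COMPONENTS) for c in SCORE_COMPONENTS}
    )
    rarity_full_percent: float = 0.1
    vus_cutoff_percent: float = 1.0
    fc_saturation: float = 4.0
    recurrence_cap: int = 3
    direction_policy: str = "under"

    def __post_init__(self) -> None:
        if set(self.weights) != set(SCORE_COMPONENTS):
            raise ValueError(f"weights must cover exactly {SCORE_COMPONENTS}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not math.isclose(sum(self.weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if not 0 < self.rarity_full_percent < self.vus_cutoff_percent:
            raise ValueError("need 0 < rarity_full_percent < vus_cutoff_percent")
        if not self.fc_saturation > 1:
            raise ValueError("fc_saturation must be > 1")
        if self.recurrence_cap < 1:
            raise ValueError("recurrence_cap must be >= 1")
        if self.direction_policy not in ("under", "over", "both"):
            raise ValueError("direction_policy must be 'under', 'over' or 'both'")


class KoDependence(str, Enum):
    SIGNIFICANT = "significant"
    SAME_DIRECTION_NS = "same_direction_ns"
    NOT_SUPPORTED = "not_supported"
    UNTESTED = "untested"


@dataclass(frozen=True)
class CandidateGene:
    """A human gene supported by both variant and expression evidence."""

    gene: str
    mouse_genes: tuple[str, ...]
    best_mouse: str
    fc: float
    direction: Direction
    variants: tuple[VariantRecord, ...]
    score_components: Mapping[str, float] = field(default_factory=dict)
    priority_score: float = math.nan
    ko_dependence: KoDependence = KoDependence.UNTESTED

    @property
    def n_patients(self) -> int:
        return len({v.patient_id for v in self.variants})

    @property
    def best_maf_percent(self) -> float:
        mafs = [0.0 if math.isnan(v.maf_percent) else v.maf_percent for v in self.variants]
        return min(mafs)


def _matches_policy(direction: Direction, policy: str) -> bool:
    if direction == Direction.UNCHANGED:
        return False
    if policy == "both":
        return True
    if policy == "under":
        return direction == Direction.UNDER_IN_ALT
    return direction == Direction.OVER_IN_ALT


def _abs_log2_fc(fc: float) -> float:
    if math.isnan(fc):
        return 0.0
    if math.isinf(fc):
        return math.inf
    return abs(math.log2(fc)) if fc > 0 else 0.0


@dataclass(frozen=True)
class CrossrefResult:
    """Candidate pool plus the bookkeeping the funnel report needs."""

    pool: tuple[CandidateGene, ...]
    unmapped_genes: tuple[str, ...]
    n_vus_genes: int
    n_mapped_genes: int


def crossref(
    vus_cohort: VusCohort,
    de_records: Iterable[DERecord],
    ortholog_map: OrthologMap,
    direction_policy: str = "under",
) -> CrossrefResult:
    """Intersect human VUS genes with mouse DE genes through the ortholog map.

    A human gene enters the pool iff at least one mapped mouse ortholog is
    classified non-unchanged in the direction the policy asks for.  When
    several orthologs qualify, the one with the largest absolute log2 fold
    change supplies the candidate's expression evidence (logged).  Human
    genes with no ortholog in the map are returned separately — never
    silently dropped.
    """
    if len(ortholog_map) == 0:
        raise ValueError("empty ortholog map")
    de_by_gene = {r.gene: r for r in de_records}
    by_gene: dict[str, list[VariantRecord]] = {}
    for r in vus_cohort.records:
        by_gene.setdefault(r.gene, []).append(r)
    pool: list[CandidateGene] = []
    unmapped: list[str] = []
    n_mapped = 0
    for gene in sorted(by_gene):
        orthologs = ortholog_map.mouse_for(gene)
        if not orthologs:
            unmapped.append(gene)
            continue
        n_mapped += 1
        qualifying = [
            de_by_gene[m]
            for m in orthologs
            if m in de_by_gene and _matches_policy(de_by_gene[m].direction, direction_policy)
        ]
        if not qualifying:
            continue
        best = max(qualifying, key=lambda r: _abs_log2_fc(r.fc))
        if len(qualifying) > 1:
            logger.info(
                "gene %s: %d qualifying orthologs, using %s (|log2 fc| largest)",
                gene, len(qualifying), best.gene,
            )
        pool.append(
            CandidateGene(
                gene=gene,
                mouse_genes=orthologs,
                best_mouse=best.gene,
                fc=best.fc,
                direction=best.direction,
                variants=tuple(by_gene[gene]),
            )
        )
    return CrossrefResult(
        pool=tuple(pool),
        unmapped_genes=tuple(unmapped),
        n_vus_genes=len(by_gene),
        n_mapped_genes=n_mapped,
    )


def _score_one(
    candidate: CandidateGene,
    config: PrioritizationConfig,
    cell_type_annotation: Mapping[str, bool] | None,
    conservation_table: Mapping[str, float] | None,
) -> CandidateGene:
    comp: dict[str, float] = {}

    maf = candidate.best_maf_percent
    if maf <= config.rarity_full_percent:
        comp["rarity"] = 1.0
    else:
        span = config.vus_cutoff_percent - config.rarity_full_percent
        comp["rarity"] = max(0.0, (config.vus_cutoff_percent - maf) / span)

    if conservation_table is not None and candidate.gene in conservation_table:
        comp["conservation"] = min(max(float(conservation_table[candidate.gene]), 0.0), 1.0)
    else:
        scores = [v.conservation for v in candidate.variants if v.conservation is not None]
        comp["conservation"] = min(max(max(scores), 0.0), 1.0) if scores else 0.5

    comp["recurrence"] = min(candidate.n_patients, config.recurrence_cap) / config.recurrence_cap

    ratios = []
    for v in candidate.variants:
        n_del, n_pred = deleterious_count(v)
        if n_pred:
            ratios.append(n_del / n_pred)
    comp["insilico"] = max(ratios) if ratios else 0.5  # no predictions: neutral

    if cell_type_annotation is None or candidate.gene not in cell_type_annotation:
        comp["cell_type"] = 0.5
    else:
        comp["cell_type"] = 1.0 if cell_type_annotation[candidate.gene] else 0.0

    comp["fc_magnitude"] = min(_abs_log2_fc(candidate.fc) / math.log2(config.fc_saturation), 1.0)

    score = sum(config.weights[c] * comp[c] for c in SCORE_COMPONENTS)
    return replace(candidate, score_components=comp, priority_score=score)


def score_candidates(
    pool: Iterable[CandidateGene],
    config: PrioritizationConfig | None = None,
    cell_type_annotation: Mapping[str, bool] | None = None,
    conservation_table: Mapping[str, float] | None = None,
) -> list[CandidateGene]:
    """Score and rank the candidate pool.

    Per-gene conservation in [0, 1] may come from ``conservation_table``
    or, failing that, from per-variant conservation scores; absent both,
    the component is neutral (0.5).  ``cell_type_annotation`` marks genes
    expressed (True) or not (False) in the male supporting lineage;
    unannotated genes are neutral.  Ties are broken by higher recurrence,
    then lower best MAF, then alphabetically.
    """
    config = config or PrioritizationConfig()
    scored = [
        _score_one(c, config, cell_type_annotation, conservation_table) for c in pool
    ]
    scored.sort(
        key=lambda c: (-c.priority_score, -c.n_patients, c.best_maf_percent, c.gene)
    )
    return scored


def annotate_ko_dependence(
    candidates: Iterable[CandidateGene],
    ko_de_records: Iterable[DERecord],
    ortholog_map: OrthologMap,
    alpha: float = 0.05,
) -> list[CandidateGene]:
    """Annotate each candidate with its knockout-comparison status.

    ``significant``: an ortholog is underexpressed in the knockout with
    ``p_adj < alpha``; ``same_direction_ns``: underexpressed but not
    significant; ``not_supported``: present in the knockout data but not
    underexpressed; ``untested``: no ortholog measured.
    """
    ko_by_gene = {r.gene: r for r in ko_de_records}
    out: list[CandidateGene] = []
    for cand in candidates:
        orthologs = ortholog_map.mouse_for(cand.gene) or cand.mouse_genes
        tested = [ko_by_gene[m] for m in orthologs if m in ko_by_gene]
        if not tested:
            out.append(replace(cand, ko_dependence=KoDependence.UNTESTED))
            continue
        under = [r for r in tested if r.fc > 1.0]
        if not under:
            out.append(replace(cand, ko_dependence=KoDependence.NOT_SUPPORTED))
            continue
        significant = [r for r in under if r.p_adj is not None and r.p_adj < alpha]
        status = KoDependence.SIGNIFICANT if significant else KoDependence.SAME_DIRECTION_NS
        out.append(replace(cand, ko_dependence=status))
    return out


@dataclass(frozen=True)
class CandidateReport:
    """Final ranked candidate table plus the per-stage funnel counts."""

    candidates: tuple[CandidateGene, ...]
    funnel: Mapping[str, int]
    parameters: Mapping[str, object] = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for rank, c in enumerate(self.candidates, start=1):
            row = {
                "rank": rank,
                "gene": c.gene,
                "mouse_gene": c.best_mouse,
                "fc": c.fc,
                "direction": c.direction.value,
                "n_patients": c.n_patients,
                "n_variants": len(c.variants),
                "best_maf_percent": c.best_maf_percent,
                "priority_score": c.priority_score,
                "ko_dependence": c.ko_dependence.value,
            }
            row.update({f"score_{k}": v for k, v in c.score_components.items()})
            rows.append(row)
        columns = [
            "rank", "gene", "mouse_gene", "fc", "direction", "n_patients", "n_variants",
            "best_maf_percent", "priority_score", "ko_dependence",
            *[f"score_{c}" for c in SCORE_COMPONENTS],
        ]
        return pd.DataFrame(rows, columns=columns)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        payload = {"funnel": dict(self.funnel), "parameters": dict(self.parameters)}
        (outdir / "funnel.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def build_report(
    candidates: Sequence[CandidateGene],
    stage_counts: Mapping[str, int],
    parameters: Mapping[str, object] | None = None,
) -> CandidateReport:
    """Assemble the ranked table and funnel into a report document."""
    return CandidateReport(
        candidates=tuple(candidates),
        funnel=dict(stage_counts),
        parameters=dict(parameters or {}),
    )
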