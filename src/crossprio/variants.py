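"""Cohort-level triage of rare variants into per-patient VUS gene sets.

The exome side of the pipeline: keep variants strictly rarer than a
population-frequency cutoff (default MAF < 1 %), optionally partition hits
in a curated known-gene list away from novel-candidate discovery, harmonize
in-silico pathogenicity calls, and build the recurrence and compound-
heterozygous indices the prioritizer consumes.

Compound-het calling is phase-naive: two or more surviving het-class
variants in one gene in one patient flag that (patient, gene) pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables_io import GeneSet, VariantRecord, Zygosity

logger = logging.getLogger(__name__)

__all__ = [
    "VusCohort",
    "filter_vus",
    "tag_insilico",
    "gene_recurrence",
    "deleterious_count",
    "DEFAULT_PREDICTION_RULES",
]

#: harmonization of raw predictor tokens to {deleterious, tolerated, unknown}
DEFAULT_PREDICTION_RULES: dict[str, str] = {
    "deleterious": "deleterious",
    "damaging": "deleterious",
    "probably_damaging": "deleterious",
    "possibly_damaging": "deleterious",
    "probably damaging": "deleterious",
    "possibly damaging": "deleterious",
    "tolerated": "tolerated",
    "benign": "tolerated",
    "neutral": "tolerated",
    "unknown": "unknown",
    "": "unknown",
}

_HARMONIZED = frozenset({"deleterious", "tolerated", "unknown"})


@dataclass(frozen=True)
class VusCohort:
    """Variants surviving the MAF filter, plus the indices built from them.

    ``records`` holds the survivors routed to novel-candidate discovery
    (i.e. outside the known-gene list when one was supplied);
    ``known_gene_records`` holds survivors in the known list, kept separate
    so known-gene hits can be reported without polluting discovery.  The
    per-patient, recurrence and compound-het indices are built over
    ``records``.
    """

    records: tuple[VariantRecord, ...]
    known_gene_records: tuple[VariantRecord, ...]
    per_patient_genes: Mapping[str, frozenset[str]]
    recurrence: Mapping[str, int]
    cmpdhet_genes: frozenset[tuple[str, str]]
    maf_cutoff_percent: float
    n_input_records: int

    @property
    def survivors(self) -> tuple[VariantRecord, ...]:
        """All records below the MAF cutoff, regardless of list membership."""
        return self.records + self.known_gene_records

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records)


def _effective_maf(record: VariantRecord) -> float:
    # missing MAF is treated as 0: rare until proven common
    if math.isnan(record.maf_percent):
        logger.warning(
            "variant %s/%s has no MAF; treated as 0", record.patient_id, record.gene
        )
        return 0.0
    return record.maf_percent


def filter_vus(
    records: Iterable[VariantRecord],
    maf_cutoff_percent: float = 1.0,
    known_gene_set: GeneSet | None = None,
) -> VusCohort:
    """Apply the strict ``MAF < cutoff`` filter and build cohort indices.

    Records in ``known_gene_set`` (when given) survive the filter but are
    partitioned into ``known_gene_records``; everything else feeds
    ``records`` and the derived per-patient, recurrence and compound-het
    indices.
    """
    if not maf_cutoff_percent > 0:
        raise ValueError("maf_cutoff_percent must be positive")
    records = list(records)
    survivors = [r for r in records if _effective_maf(r) < maf_cutoff_percent]
    if known_gene_set is not None:
        known = tuple(r for r in survivors if r.gene in known_gene_set)
        novel = tuple(r for r in survivors if r.gene not in known_gene_set)
    else:
        known = ()
        novel = tuple(survivors)

    per_patient: dict[str, set[str]] = {}
    het_counts: dict[tuple[str, str], int] = {}
    for r in novel:
        per_patient.setdefault(r.patient_id, set()).add(r.gene)
        if r.zygosity in (Zygosity.HET, Zygosity.CMPD_HET):
            het_counts[(r.patient_id, r.gene)] = het_counts.get((r.patient_id, r.gene), 0) + 1
    recurrence: dict[str, int] = {}
    for genes in per_patient.values():
        for g in genes:
            recurrence[g] = recurrence.get(g, 0) + 1
    cmpdhet = frozenset(k for k, n in het_counts.items() if n >= 2)
    return VusCohort(
        records=novel,
        known_gene_records=known,
        per_patient_genes={p: frozenset(g) for p, g in per_patient.items()},
        recurrence=recurrence,
        cmpdhet_genes=cmpdhet,
        maf_cutoff_percent=maf_cutoff_percent,
        n_input_records=len(records),
    )


def tag_insilico(
    records: Iterable[VariantRecord],
    rules: Mapping[str, str] | None = None,
    strict: bool = False,
) -> list[VariantRecord]:
    """Harmonize raw in-silico predictor calls on each record.

    ``rules`` maps raw tokens (case-insensitive) to one of ``deleterious``,
    ``tolerated`` or ``unknown``.  Unrecognized tokens raise under
    ``strict=True`` and harmonize to ``unknown`` otherwise.
    """
    rules = {k.lower(): v for k, v in (rules or DEFAULT_PREDICTION_RULES).items()}
    if not set(rules.values()) <= _HARMONIZED:
        raise ValueError(f"rule targets must be in {sorted(_HARMONIZED)}")
    out: list[VariantRecord] = []
    for r in records:
        harmonized: dict[str, str] = {}
        for predictor, raw in r.predictions.items():
            token = str(raw).strip().lower()
            if token in _HARMONIZED:
                harmonized[predictor] = token
            elif token in rules:
                harmonized[predictor] = rules[token]
            elif strict:
                raise ValueError(f"unknown prediction token {raw!r} for {predictor}")
            else:
                harmonized[predictor] = "unknown"
        out.append(replace(r, predictions=harmonized))
    return out


def deleterious_count(record: VariantRecord) -> tuple[int, int]:
    """Return (number of 'deleterious' calls, number of predictors with a call).

    Predictors whose harmonized call is ``unknown`` still count toward the
    denominator; records with no predictions return ``(0, 0)``.
    """
    calls = list(record.predictions.values())
    return sum(1 for c in calls if c == "deleterious"), len(calls)


def gene_recurrence(cohort: VusCohort) -> pd.DataFrame:
    """Per-gene distinct-patient and variant-row counts over the cohort.

    Returns a DataFrame indexed by gene with columns ``n_patients`` and
    ``n_variants``, sorted by descending recurrence then gene symbol.
    """
    rows: dict[str, dict[str, set | int]] = {}
    for r in cohort.records:
        entry = rows.setdefault(r.gene, {"patients": set(), "n_variants": 0})
        entry["patients"].add(r.patient_id)
        entry["n_variants"] += 1
    df = pd.DataFrame(
        {
            "n_patients": {g: len(e["patients"]) for g, e in rows.items()},
            "n_variants": {g: e["n_variants"] for g, e in rows.items()},
        },
        dtype=int,
    )
    df.index.name = "gene"
    # descending by recurrence, alphabetical within ties
    df = df.sort_index(kind="stable")
    return df.sort_values(["n_patients", "n_variants"], ascending=False, kind="stable")
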