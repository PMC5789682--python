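"""Synthetic study generator: every input the pipeline consumes, with the
statistical structure the analysis assumes, plus the planted ground truth.

The generator emulates a cross-species candidate-gene study:

* a 32-patient rare-disease exome cohort in which each patient carries
  VUS in 30-1100 genes under a mixture MAF distribution (a point mass at
  exactly 0 plus a log-uniform tail), with ``n_causal`` planted causal
  genes carrying very rare (MAF <= 0.1 %), in-silico-deleterious variants
  and at least one compound-heterozygous event;
* a two-group gonadal FPKM matrix (reference ``YB6`` males vs
  undervirilized ``YPOS`` males) with the causal genes' mouse orthologs
  planted ``causal_fc``-fold under-expressed, decoy under/over-expressed
  genes, and log-normal multiplicative noise;
* a 3 + 3 replicate wild-type vs knockout count matrix with negative-
  binomial noise in which a planted fraction of the causal genes (default
  7/15) is strongly knockout-dependent and a further fraction is mildly
  shifted (same direction, not expected to reach significance);
* the human-mouse ortholog map (with deliberate one-to-many and unmapped
  cases) and a male-supporting-lineage cell-type annotation.

Everything is a pure function of ``SimulationConfig.seed``: the same seed
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import (
    ExpressionMatrix,
    OrthologMap,
    VariantRecord,
    Zygosity,
    write_expression_matrix,
    write_ortholog_map,
    write_variant_table,
)

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate_study", "simulate_cohort",
           "simulate_expression", "write_study"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study conditions the pipeline was designed for: a
    32-patient cohort, 30-1100 VUS genes per patient, 4-fold planted
    under-expression, a 3 vs 3 knockout design with negative-binomial
    dispersion 0.05, and 7/15 of the causal genes knockout-dependent.
    ``fpkm_sigma`` is the log-normal noise sigma (natural log) on FPKM —
    small, because pooled-embryo gonad samples average away most
    biological variability.
    """

    seed: int = 0
    n_patients: int = 32
    n_genes_human: int = 20000
    n_genes_mouse: int = 20000
    vus_genes_per_patient: tuple[int, int] = (30, 1100)
    maf_zero_mass: float = 0.2
    maf_log_range_percent: tuple[float, float] = (1e-4, 1.0)
    n_causal: int = 20
    causal_fc: float = 4.0
    causal_direction: str = "under"
    causal_maf_max_percent: float = 0.1
    fpkm_sigma: float = 0.15
    fpkm_replicates: int = 2
    decoy_de_fraction: float = 0.025
    decoy_fc_range: tuple[float, float] = (1.6, 3.2)
    ko_replicates: int = 3
    nb_dispersion: float = 0.05
    ko_dependent_fraction: float = 7.0 / 15.0
    ko_mild_fraction: float = 6.0 / 15.0
    ko_fc: float = 4.0
    ko_mild_fc: float = 1.3
    ortholog_mapped_fraction: float = 0.7
    one_to_many_fraction: float = 0.02
    background_deleterious_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_causal > min(self.n_genes_human, self.n_genes_mouse):
            raise ValueError("n_causal exceeds the gene universe")
        lo, hi = self.vus_genes_per_patient
        if not 0 < lo <= hi:
            raise ValueError("invalid vus_genes_per_patient range")
        if hi + self.n_causal > self.n_genes_human:
            raise ValueError("per-patient VUS range incompatible with n_genes_human")
        if not 0 <= self.maf_zero_mass <= 1:
            raise ValueError("maf_zero_mass must be in [0, 1]")
        if self.causal_fc <= 1 or self.ko_fc <= 1:
            raise ValueError("planted fold changes must exceed 1")
        if self.ko_dependent_fraction + self.ko_mild_fraction > 1:
            raise ValueError("ko-dependent and mild fractions exceed the causal set")
        if self.fpkm_sigma < 0 or self.nb_dispersion < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.causal_direction not in ("under", "over"):
            raise ValueError("causal_direction must be 'under' or 'over'")
        if self.fpkm_replicates < 1 or self.ko_replicates < 2:
            raise ValueError("need >=1 FPKM replicate and >=2 knockout replicates")


def _human_symbol(i: int) -> str:
    return f"GENE{i:04d}"


def _mouse_symbol(i: int) -> str:
    return f"Gene{i:04d}"


@dataclass(frozen=True)
class SyntheticStudy:
    """All generated inputs plus the planted truth."""

    config: SimulationConfig
    variant_records: tuple[VariantRecord, ...]
    fpkm: ExpressionMatrix
    ko_counts: ExpressionMatrix
    ortholog_map: OrthologMap
    cell_type_annotation: Mapping[str, bool]
    truth: Mapping[str, object]


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study from one seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n_shared = min(config.n_genes_human, config.n_genes_mouse)

    # --- shared gene universe and planted causal set -----------------------
    causal_idx = np.sort(rng.choice(np.arange(1, n_shared + 1), size=config.n_causal,
                                    replace=False))
    causal_human = [_human_symbol(i) for i in causal_idx]
    causal_mouse = [_mouse_symbol(i) for i in causal_idx]
    causal_set = set(causal_idx.tolist())

    # --- ortholog map ------------------------------------------------------
    other_idx = np.array([i for i in range(1, n_shared + 1) if i not in causal_set])
    n_extra = int(round(config.ortholog_mapped_fraction * len(other_idx)))
    mapped_extra = np.sort(rng.choice(other_idx, size=n_extra, replace=False))
    mapped_idx = np.concatenate([causal_idx, mapped_extra])
    pairs = [(_human_symbol(i), _mouse_symbol(i)) for i in np.sort(mapped_idx)]
    # deliberate one-to-many cases: a second mouse symbol for a few human genes
    n_multi = int(round(config.one_to_many_fraction * len(pairs)))
    if n_multi:
        multi_pick = rng.choice(len(pairs), size=n_multi, replace=False)
        for j in np.sort(multi_pick):
            human, mouse = pairs[j]
            pairs.append((human, mouse + "b"))
    ortholog_map = OrthologMap(pairs, provenance="synthetic")
    mapped_set = set(mapped_idx.tolist())

    # --- cohort variants ----------------------------------------------------
    patients = [f"PT{j:03d}" for j in range(1, config.n_patients + 1)]
    lo_maf, hi_maf = config.maf_log_range_percent
    records: list[VariantRecord] = []
    carriers_by_gene: dict[str, list[str]] = {}

    def rare_maf() -> float:
        if rng.random() < config.maf_zero_mass:
            return 0.0
        return float(np.exp(rng.uniform(math.log(lo_maf),
                                        math.log(config.causal_maf_max_percent))))

    def background_maf() -> float:
        if rng.random() < config.maf_zero_mass:
            return 0.0
        return float(np.exp(rng.uniform(math.log(lo_maf), math.log(hi_maf))))

    def background_call() -> str:
        u = rng.random()
        if u < config.background_deleterious_prob:
            return "deleterious"
        if u < config.background_deleterious_prob + 0.6:
            return "tolerated"
        return "unknown"

    variant_counter = 0

    def make_variant(patient: str, gene: str, zyg: Zygosity, maf: float,
                     predictions: Mapping[str, str]) -> VariantRecord:
        nonlocal variant_counter
        variant_counter += 1
        return VariantRecord(
            patient_id=patient,
            gene=gene,
            zygosity=zyg,
            hgvs_c=f"c.{variant_counter}G>A",
            hgvs_p=f"p.Ala{variant_counter}Thr",
            maf_percent=maf,
            predictions=dict(predictions),
        )

    planted_for_patient: dict[str, set[str]] = {p: set() for p in patients}
    for gi, gene in enumerate(causal_human):
        n_carriers = int(rng.integers(1, 4))
        chosen = rng.choice(config.n_patients, size=n_carriers, replace=False)
        for pi in np.sort(chosen):
            patient = patients[int(pi)]
            records.append(
                make_variant(patient, gene, Zygosity.HET, rare_maf(),
                             {"sift": "deleterious", "polyphen": "deleterious"})
            )
            planted_for_patient[patient].add(gene)
            carriers_by_gene.setdefault(gene, []).append(patient)

    # one planted compound-het event: a second het-class variant in the same
    # (patient, gene) so the phase-naive caller flags it
    compound_het_event: list[str] | None = None
    if causal_human:
        first_gene = causal_human[0]
        first_patient = carriers_by_gene[first_gene][0]
        records.append(
            make_variant(first_patient, first_gene, Zygosity.CMPD_HET, rare_maf(),
                         {"sift": "deleterious", "polyphen": "deleterious"})
        )
        compound_het_event = [first_patient, first_gene]

    noncausal_human = np.array([i for i in range(1, config.n_genes_human + 1)
                                if i not in causal_set])
    lo_n, hi_n = config.vus_genes_per_patient
    for patient in patients:
        n_bg = int(rng.integers(lo_n, hi_n - config.n_causal + 1))
        bg_genes = rng.choice(noncausal_human, size=n_bg, replace=False)
        for i in np.sort(bg_genes):
            zyg = Zygosity.HET if rng.random() < 0.9 else Zygosity.HOM
            records.append(
                make_variant(patient, _human_symbol(int(i)), zyg, background_maf(),
                             {"sift": background_call(), "polyphen": background_call()})
            )

    # --- FPKM matrix (two groups) ------------------------------------------
    mouse_genes = [_mouse_symbol(i) for i in range(1, config.n_genes_mouse + 1)]
    base = np.exp(rng.normal(math.log(20.0), 1.0, size=config.n_genes_mouse))
    noncausal_mouse = np.array([i for i in range(1, config.n_genes_mouse + 1)
                                if i not in causal_set])
    n_decoy = int(round(config.decoy_de_fraction * config.n_genes_mouse))
    decoy_pick = rng.choice(noncausal_mouse, size=2 * n_decoy, replace=False)
    decoy_under = np.sort(decoy_pick[:n_decoy])
    decoy_over = np.sort(decoy_pick[n_decoy:])
    decoy_fc = rng.uniform(*config.decoy_fc_range, size=2 * n_decoy)

    mean_ref = base.copy()
    planted = np.concatenate([causal_idx, decoy_under, decoy_over])
    mean_ref[planted - 1] = np.maximum(mean_ref[planted - 1], 5.0)  # keep fc visible
    mean_alt = mean_ref.copy()
    if config.causal_direction == "under":
        mean_alt[causal_idx - 1] = mean_ref[causal_idx - 1] / config.causal_fc
    else:
        mean_alt[causal_idx - 1] = mean_ref[causal_idx - 1] * config.causal_fc
    mean_alt[decoy_under - 1] = mean_ref[decoy_under - 1] / decoy_fc[:n_decoy]
    mean_alt[decoy_over - 1] = mean_ref[decoy_over - 1] * decoy_fc[n_decoy:]

    def noisy(mean: np.ndarray, n_rep: int) -> np.ndarray:
        noise = (
            np.exp(rng.normal(0.0, config.fpkm_sigma, size=(mean.size, n_rep)))
            if config.fpkm_sigma > 0
            else np.ones((mean.size, n_rep))
        )
        return mean[:, None] * noise

    ref_cols = [f"YB6_{j + 1}" for j in range(config.fpkm_replicates)]
    alt_cols = [f"YPOS_{j + 1}" for j in range(config.fpkm_replicates)]
    fpkm_values = np.hstack([noisy(mean_ref, len(ref_cols)), noisy(mean_alt, len(alt_cols))])
    fpkm = ExpressionMatrix(
        values=pd.DataFrame(fpkm_values, index=mouse_genes,
                            columns=ref_cols + alt_cols),
        groups={**{c: "YB6" for c in ref_cols}, **{c: "YPOS" for c in alt_cols}},
        unit="FPKM",
        species="mouse",
    )

    # --- knockout count matrix (3 vs 3) -------------------------------------
    n_dep = int(round(config.ko_dependent_fraction * config.n_causal))
    n_mild = int(round(config.ko_mild_fraction * config.n_causal))
    ko_dependent = causal_idx[:n_dep]
    ko_mild = causal_idx[n_dep:n_dep + n_mild]
    ko_base = np.exp(rng.normal(math.log(300.0), 1.0, size=config.n_genes_mouse))
    ko_base[causal_idx - 1] = np.maximum(ko_base[causal_idx - 1], 200.0)
    ko_mu_wt = ko_base
    ko_mu_ko = ko_base.copy()
    ko_mu_ko[ko_dependent - 1] = ko_mu_wt[ko_dependent - 1] / config.ko_fc
    ko_mu_ko[ko_mild - 1] = ko_mu_wt[ko_mild - 1] / config.ko_mild_fc

    wt_cols = [f"XY_WT_{j + 1}" for j in range(config.ko_replicates)]
    ko_cols = [f"XY_KO_{j + 1}" for j in range(config.ko_replicates)]
    depth = rng.uniform(0.7, 1.3, size=len(wt_cols) + len(ko_cols))

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion == 0:
            return rng.poisson(mu)
        size = 1.0 / config.nb_dispersion
        return rng.negative_binomial(size, size / (size + mu))

    count_cols = []
    for j, col in enumerate(wt_cols + ko_cols):
        mu = (ko_mu_wt if j < len(wt_cols) else ko_mu_ko) * depth[j]
        count_cols.append(nb_draw(mu))
    ko_counts = ExpressionMatrix(
        values=pd.DataFrame(np.column_stack(count_cols), index=mouse_genes,
                            columns=wt_cols + ko_cols),
        groups={**{c: "XY_WT" for c in wt_cols}, **{c: "XY_KO" for c in ko_cols}},
        unit="counts",
        species="mouse",
    )

    # --- cell-type annotation ----------------------------------------------
    cell_type: dict[str, bool] = {g: True for g in causal_human}
    n_negative = int(round(0.05 * config.n_genes_human))
    neg_pick = rng.choice(noncausal_human, size=n_negative, replace=False)
    for i in np.sort(neg_pick):
        cell_type[_human_symbol(int(i))] = False

    truth = {
        "causal_human": causal_human,
        "causal_mouse": causal_mouse,
        "carriers_by_gene": {g: sorted(set(ps)) for g, ps in carriers_by_gene.items()},
        "compound_het_event": compound_het_event,
        "ko_dependent_mouse": [_mouse_symbol(i) for i in ko_dependent],
        "ko_mild_mouse": [_mouse_symbol(i) for i in ko_mild],
        "decoy_under_mouse": [_mouse_symbol(i) for i in decoy_under],
        "decoy_over_mouse": [_mouse_symbol(i) for i in decoy_over],
        "unmapped_human": sorted(
            _human_symbol(i) for i in range(1, config.n_genes_human + 1)
            if i not in mapped_set
        ),
    }
    return SyntheticStudy(
        config=config,
        variant_records=tuple(records),
        fpkm=fpkm,
        ko_counts=ko_counts,
        ortholog_map=ortholog_map,
        cell_type_annotation=cell_type,
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig | None = None):
    """Variant table + truth subset (cohort half of the study)."""
    study = simulate_study(config)
    truth = {k: study.truth[k] for k in
             ("causal_human", "carriers_by_gene", "compound_het_event")}
    return study.variant_records, truth


def simulate_expression(config: SimulationConfig | None = None):
    """FPKM matrix, knockout counts, ortholog map + truth subset."""
    study = simulate_study(config)
    truth = {k: study.truth[k] for k in
             ("causal_mouse", "ko_dependent_mouse", "ko_mild_mouse",
              "decoy_under_mouse", "decoy_over_mouse")}
    return study.fpkm, study.ko_counts, study.ortholog_map, truth


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file plus ``truth.json``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "ko_counts": outdir / "ko_counts.tsv",
        "ortholog_map": outdir / "ortholog_map.tsv",
        "cell_type": outdir / "cell_type.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "simulation_config.json",
    }
    write_variant_table(study.variant_records, paths["variants"])
    write_expression_matrix(study.fpkm, paths["fpkm"])
    write_expression_matrix(study.ko_counts, paths["ko_counts"])
    write_ortholog_map(study.ortholog_map, paths["ortholog_map"])
    with open(paths["cell_type"], "w", encoding="utf-8") as fh:
        fh.write("gene\texpressed_male_lineage\n")
        for gene in sorted(study.cell_type_annotation):
            fh.write(f"{gene}\t{'yes' if study.cell_type_annotation[gene] else 'no'}\n")
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    paths["config"].write_text(json.dumps(asdict(study.config), indent=2, sort_keys=True))
    return paths
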