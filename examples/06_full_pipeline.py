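"""End-to-end run on a synthetic study with planted ground truth.

Simulates the whole study (exome cohort, gonadal FPKM matrix, knockout
counts, ortholog map), runs every pipeline stage, and checks recovery of
the planted causal genes.
"""

from crossprio import SimulationConfig, run_pipeline_objects, simulate_study

study = simulate_study(SimulationConfig(seed=7))
report = run_pipeline_objects(
    list(study.variant_records),
    study.fpkm,
    study.ortholog_map,
    study.ko_counts,
    cell_type_annotation=study.cell_type_annotation,
)

print("funnel (records/genes surviving each stage):")
for key, value in report.funnel.items():
    print(f"  {key:22s} {value}")

causal = set(study.truth["causal_human"])
pool = {c.gene for c in report.candidates}
top = [c.gene for c in report.candidates[: len(causal)]]
print(f"\nplanted causal genes in candidate pool: {len(causal & pool)}/{len(causal)}")
print(f"planted causal genes in top-{len(causal)} ranks: {len(causal & set(top))}")
ko_sig = [c.gene for c in report.candidates if c.ko_dependence.value == "significant"]
print(f"candidates flagged knockout-dependent (significant): {len(ko_sig)}")
print("\nThe funnel shrinks monotonically; planted genes carry rare deleterious")
print("variants plus 4-fold underexpression, so they reach the top ranks.")
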