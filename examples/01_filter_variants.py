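"""Filter the bundled 46,XY DSD cohort variant table to its VUS gene sets.

Loads the 27 candidate-gene variants observed across the 32-patient
cohort, applies the strict MAF < 1 % filter, and prints the recurrence
table: genes seen in several unrelated patients are stronger candidates.
"""

from crossprio import filter_vus, gene_recurrence, tag_insilico
from crossprio.datasets import load_cohort_variants

records = tag_insilico(load_cohort_variants())
cohort = filter_vus(records, maf_cutoff_percent=1.0)

print(f"records in: {cohort.n_input_records}, surviving MAF < 1%: "
      f"{len(cohort.survivors)}, distinct genes: {len(cohort.genes)}")
print(f"compound-het events (phase-naive): {sorted(cohort.cmpdhet_genes)}")
print()
print(gene_recurrence(cohort).head(6))
print()
print("n_patients counts distinct carriers; genes recurrent across unrelated")
print("patients (ADAMTS16, LGR5, MYBL1 with 3 each) top the recurrence strata.")
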