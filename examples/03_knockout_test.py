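"""TMM-normalized replicate-based DE test on the wild-type vs knockout counts.

The 3 + 3 negative-binomial count matrix carries a planted subset of
strongly knockout-dependent genes.  The test TMM-normalizes, moves to
log2 CPM, applies a variance-moderated t test and BH correction.
"""

from crossprio import SimulationConfig, de_test_adjusted, simulate_expression, tmm_normalize

_, ko_counts, _, truth = simulate_expression(SimulationConfig(seed=42))

factors = tmm_normalize(ko_counts)
print("TMM factors (geometric mean 1):")
print(factors.factors.round(4).to_string())

records = de_test_adjusted(ko_counts, "XY_WT", "XY_KO", alpha=0.05)
significant = {r.gene for r in records if r.p_adj < 0.05 and r.fc > 1}
dependent = set(truth["ko_dependent_mouse"])
print(f"\ngenes significantly underexpressed in the knockout (p_adj < 0.05): "
      f"{len(significant)}")
print(f"planted knockout-dependent genes detected: "
      f"{len(dependent & significant)}/{len(dependent)}")
print("\nA significant call means lower expression in knockout gonads after")
print("normalization — evidence the gene sits downstream of the knocked-out")
print("transcription factor.")
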