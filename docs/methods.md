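# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the `crossprio` pipeline.

## Problem setting

Exome sequencing of rare-disease cohorts leaves most patients with
hundreds of variants of unknown significance (VUS) and no diagnosis. The
pipeline formalizes a cross-species triage: genes that are both
(a) VUS-carrying in patients and (b) mis-expressed in the developing
gonad of a disease-model mouse are promoted to candidates, on the
premise that genes required for normal organogenesis are expressed at
the right time and place and drop in expression when the program fails.
The motivating application is 46,XY gonadal dysgenesis, with the
undervirilized B6-Y^POS mouse as the expression model and an
*Amh-Cre Sox9^flox/flox* knockout as the downstream-regulator probe, but
every stage is generic over the supplied tables.

## Variant filtering

Variants are kept when `maf_percent < cutoff` (strict inequality;
default 1 on the percent scale). A missing MAF is treated as 0 — rare
until proven common — and logged. The later, softer rarity preference
(MAF ≤ 0.1 %) is deliberately *not* a hard filter: observed cohorts
retain candidate variants at 0.3–0.8 %, so rarity enters the priority
score instead. Compound-het calling is phase-naive by design: two or
more surviving het-class variants in one gene in one patient flag the
pair; no phasing information is consumed. When a curated known-gene list
is supplied, its hits survive filtering but are partitioned out of
novel-candidate discovery, since their interpretation follows a
diagnostic rather than a discovery path.

Human symbols are uppercased and mouse symbols title-cased on ingest;
the two namespaces are only ever connected through an explicit ortholog
map, never by case-folding, because symbol case conventions are not a
reliable orthology signal.

## Fold-change differential expression

Pooled-sample FPKM designs carry no within-group replication, so DE is a
ratio of group means: `fc = (mean_ref + c)/(mean_alt + c)` with
pseudocount `c = 0.1` FPKM (configurable, reported in output). The
pseudocount keeps ratios finite for genes silent in one group — common
at early developmental stages — while perturbing moderately expressed
genes by < 1 % at 10 FPKM. Classification is symmetric: under-expressed
in the alternate group when `fc ≥ cutoff`, over-expressed when
`fc ≤ 1/cutoff`. Escalation from 1.5 to 2.0 re-classifies the same
records; the non-unchanged set can only shrink. With `c = 0`, a
zero/zero gene is reported as undefined (`fc = nan`, unchanged) rather
than crashing or being dropped.

## TMM normalization

Between-sample normalization of count matrices uses the trimmed mean of
M-values. For sample *k* against reference *r*, with counts `Y` and
library sizes `N`:

    M_g = log2( (Y_gk/N_k) / (Y_gr/N_r) )
    A_g = 0.5 · log2( (Y_gk/N_k) · (Y_gr/N_r) )
    v_g = (N_k − Y_gk)/(N_k Y_gk) + (N_r − Y_gr)/(N_r Y_gr)

Genes with a zero count in either sample are excluded from the pair.
After double trimming (30 % of M-values, 5 % of A-values, rank-based
with average ties), the factor is `2^( Σ M_g/v_g / Σ 1/v_g )` — an
inverse-delta-method-variance weighted mean. Factors are re-centered to
geometric mean 1. The reference sample, when not given, is the one whose
75th count-fraction percentile is closest to the mean across samples.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
at least 9 decimal places on the toy matrices frozen in the test suite.
Because the precision weights depend on raw counts, TMM factors are only
approximately invariant to a pure depth change (exactly invariant in the
unweighted M-values).

## Knockout differential-expression test

Counts are TMM-normalized and transformed to `log2(CPM + 0.5)` over
effective library sizes. The default per-gene test is a two-sample t
with empirical-Bayes variance moderation: per-gene pooled variances
`s²_g` (df `d = n₁+n₂−2`) are shrunk toward a prior `s₀²` with prior df
`d₀`, both estimated by matching the moments of `log s²_g` to a scaled-F
model (trigamma inversion by Newton iteration), giving
`s²_post = (d₀s₀² + d s²_g)/(d₀ + d)` and `d + d₀` degrees of freedom.
This choice is deliberate: with three replicates per group and thousands
of genes under BH correction, an unmoderated Welch test has essentially
no power at realistic effect sizes — per-gene variance estimates at
n = 3 are too noisy — whereas variance moderation is the standard remedy
in this design regime. The unmoderated Welch test remains available
(`method="welch"`) for sensitivity analyses. P values are BH-adjusted
across all tested genes; significance means `p_adj < α` (default 0.05).
Genes with zero variance and zero difference report p = 1. Direction for
these records is sign-based (`fc = 2^(Δ log2 CPM)`, `fc > 1` meaning
lower in the knockout).

Candidates are annotated `significant` (ortholog under-expressed in the
knockout with `p_adj < α`), `same_direction_ns`, `not_supported`
(measured, wrong direction), or `untested` (absent from the matrix).

## Cross-referencing and the priority score

A human gene enters the candidate pool iff at least one mapped mouse
ortholog is non-unchanged in the policy direction (default:
under-expressed only, matching the observation that disease-relevant
genes cluster in the under-expressed arm). With one-to-many orthology
the ortholog with the largest |log2 fc| supplies the expression
evidence; the choice is logged. Unmapped genes are returned as a
separate list with counts.

The qualitative multi-criteria triage is formalized as a weighted
additive score over six components, each in [0, 1]:

| component     | definition                                               | default |
|---------------|----------------------------------------------------------|---------|
| rarity        | 1 at MAF ≤ 0.1 %, linear decay to 0 at the VUS cutoff    | knee 0.1 %, cutoff 1 % |
| conservation  | provided normalized score, else neutral                  | 0.5 when absent |
| recurrence    | min(n_patients, cap)/cap                                 | cap 3 |
| insilico      | max over variants of deleterious_calls/predictor_calls   | 0.5 when no calls |
| cell_type     | 1 if expressed in the male supporting lineage, 0 if not  | 0.5 when unannotated |
| fc_magnitude  | min(\|log2 fc\| / log2 saturation, 1)                    | saturation 4× |

Weights default to 1/6 each and must sum to 1. A "literature
availability" criterion is excluded as non-computable; its notional
weight is absorbed by renormalization. Neutral (0.5) defaults for
missing evidence keep absence-of-annotation from acting as evidence in
either direction. Ties are broken by higher recurrence, then lower best
MAF, then alphabetically — fully deterministic output.

## Enrichment

Over-representation is the upper-tail hypergeometric probability
`P[X ≥ k]` for an overlap of `k` query genes with a `K`-gene term in an
`N`-gene universe at query size `n`, computed via the survival function.
Query genes outside the universe are dropped with a warning; `k = 0`
terms report p = 1. BH is the default correction (Bonferroni and none
available) and is recorded in the output. No ontology-graph propagation
is performed; the annotation is taken as given, keeping results
independent of any particular ontology release.

## qPCR quantification

Standard curves are ordinary least squares of Ct on input amount over a
dilution series, duplicate wells averaged per point first. The literal
linear-amount axis is the default; a log10-axis switch is provided since
serial-dilution designs are usually analyzed on the log scale (the
worked example uses it). Quantities come from inverting the fitted line;
values are reported on the fitted axis. Concordance between sequencing
and qPCR fold changes is the fraction of shared genes whose log fold
changes agree in sign.

## Synthetic study generator

`SimulationConfig` defaults describe the study conditions the pipeline
targets:

* 32 patients; per-patient VUS gene counts uniform on 30–1100 over a
  20,000-gene universe. The universe size matters: the quoted per-case
  VUS ranges arise at whole-exome scale, and only at that scale does
  background gene recurrence stay realistically low (~1 carrier per
  gene) so that the recurrence criterion discriminates.
* MAF mixture: a 0.2 point mass at exactly 0 (very rare variants are
  printed as 0 in population databases) plus a log-uniform tail on
  (10⁻⁴, 1) percent. Planted causal variants draw from the ≤ 0.1 % tail
  and carry deleterious calls from both in-silico predictors; one
  compound-het event is always planted.
* 20 causal genes at 4-fold under-expression; decoy DE genes at 2.5 %
  of the transcriptome per direction with fold changes uniform on
  (1.6, 3.2), so escalation to 2× prunes some of them.
* FPKM noise is log-normal with σ = 0.15 (natural log): pooled-embryo
  gonad samples (tens of gonads per pool) average away most biological
  variability.
* Knockout design: 3 vs 3 replicates, negative-binomial dispersion
  0.05, per-sample depth factors uniform on (0.7, 1.3); 7/15 of the
  causal genes are strongly knockout-dependent (4-fold) and a further
  6/15 mildly shifted (1.3-fold, same direction, expected
  non-significant) — mirroring the "13 of 15 down, 7 significant"
  structure of the motivating study.

Everything derives from a single seed; identical seeds give
byte-identical outputs. What the generator does *not* emulate: linkage
between variants, consequence-type structure, gene length and GC biases
in counts, correlated expression modules, and real ortholog-map
incompleteness patterns. Passing the planted-recovery suite therefore
demonstrates the pipeline's set logic, ranking behaviour and statistical
calibration under the stated noise model — not performance on real
cohorts.

## Problem sizes used in the test suite

The planted-recovery suite runs 50 seeds of the full default-scale study
(20,000 genes, 32 patients) — about half a minute on one CPU. Randomized
invariant checks use 1,000 cases at small scale (dozens of genes) since
the properties are scale-free. The brute-force hypergeometric comparison
enumerates every configuration up to a 12-gene universe.

## Known limitations

* The fold-change stage has no error model; with pooled designs there
  is no within-group variance to exploit, which is why the knockout
  comparison (with replicates) carries the inferential weight.
* ACMG-style pathogenicity classification is out of scope; known-gene
  hits are routed to a report, not adjudicated.
* HGVS strings are carried verbatim (prefix-checked only); no
  normalization or liftover.
* The VCF dialect requires pre-annotated gene symbols and allele
  frequencies in INFO; the package does not annotate raw variant calls
  against transcript models.
* The score's weights are a modelling convenience, not fitted
  quantities; rank stability under weight perturbation should be checked
  when applying the pipeline to a new cohort.
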