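"""Differential expression: fold-change classification, cutoff escalation,
TMM normalization, the replicate-based knockout test, and qPCR support."""

import math

import numpy as np
import pandas as pd
import pytest

from crossprio import (
    DERecord,
    Direction,
    ExpressionMatrix,
    ct_to_quantity,
    de_test_adjusted,
    escalate_cutoff,
    fit_standard_curve,
    fold_change_de,
    qpcr_concordance,
    tmm_normalize,
)
from conftest import make_matrix


def _two_group(values_ref, values_alt, unit="FPKM", index=None):
    data = {"R1": [v[0] for v in values_ref], "R2": [v[1] for v in values_ref],
            "A1": [v[0] for v in values_alt], "A2": [v[1] for v in values_alt]}
    groups = {"R1": "ref", "R2": "ref", "A1": "alt", "A2": "alt"}
    return make_matrix(data, groups, unit=unit, index=index)


class TestFoldChange:
    def test_equal_means_are_unchanged(self):
        m = _two_group([(5.0, 5.0)], [(5.0, 5.0)])
        (r,) = fold_change_de(m, "ref", "alt", fc_cutoff=1.5, pseudocount=0.0)
        assert r.fc == 1.0 and r.direction is Direction.UNCHANGED

    def test_planted_eightfold_underexpression(self):
        m = _two_group([(8.0, 8.0)], [(1.0, 1.0)])
        (r,) = fold_change_de(m, "ref", "alt", fc_cutoff=2.0, pseudocount=0.0)
        assert r.direction is Direction.UNDER_IN_ALT and r.fc == 8.0

    def test_hundred_gene_noise_free_classification(self):
        """10 planted 4x under + 10 planted 4x over are exactly the
        non-unchanged calls; expectations computed by per-gene arithmetic."""
        rng = np.random.default_rng(11)
        base = rng.uniform(2, 50, size=100)
        alt = base.copy()
        alt[:10] = base[:10] / 4.0
        alt[10:20] = base[10:20] * 4.0
        genes = [f"Gene{i:03d}" for i in range(100)]
        m = _two_group([(b, b) for b in base], [(a, a) for a in alt], index=genes)
        records = fold_change_de(m, "ref", "alt", fc_cutoff=1.5, pseudocount=0.1)
        # independent oracle: direct ratio arithmetic per gene
        for i, r in enumerate(records):
            expected_fc = (base[i] + 0.1) / (alt[i] + 0.1)
            assert r.fc == pytest.approx(expected_fc, rel=1e-12)
        called = {r.gene: r.direction for r in records}
        assert [g for g, d in called.items() if d is Direction.UNDER_IN_ALT] == genes[:10]
        assert [g for g, d in called.items() if d is Direction.OVER_IN_ALT] == genes[10:20]

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        vals_ref = rng.lognormal(2, 1, size=(30, 2))
        vals_alt = rng.lognormal(2, 1, size=(30, 2))
        m = _two_group(list(vals_ref), list(vals_alt))
        fwd = fold_change_de(m, "ref", "alt", 1.5)
        rev = fold_change_de(m, "alt", "ref", 1.5)
        swap = {Direction.UNDER_IN_ALT: Direction.OVER_IN_ALT,
                Direction.OVER_IN_ALT: Direction.UNDER_IN_ALT,
                Direction.UNCHANGED: Direction.UNCHANGED}
        for f, r in zip(fwd, rev):
            assert r.fc == pytest.approx(1.0 / f.fc, rel=1e-12)
            assert r.direction is swap[f.direction]

    def test_zero_denominator_without_pseudocount(self):
        m = _two_group([(4.0, 4.0), (0.0, 0.0)], [(0.0, 0.0), (0.0, 0.0)],
                       index=["Genea", "Geneb"])
        ra, rb = fold_change_de(m, "ref", "alt", 1.5, pseudocount=0.0)
        assert math.isinf(ra.fc) and ra.direction is Direction.UNDER_IN_ALT
        assert math.isnan(rb.fc) and rb.direction is Direction.UNCHANGED
        assert not rb.fc_defined

    def test_absent_group_errors(self):
        m = _two_group([(1.0, 1.0)], [(1.0, 1.0)])
        with pytest.raises(ValueError, match="no samples"):
            fold_change_de(m, "ref", "nonexistent")


class TestEscalateCutoff:
    @staticmethod
    def _records(fcs, cutoff=1.5):
        from crossprio.expression import classify_direction

        return [DERecord(gene=f"Gene{i:02d}", mean_ref=fc, mean_alt=1.0, fc=fc,
                         direction=classify_direction(fc, cutoff), cutoff_used=cutoff)
                for i, fc in enumerate(fcs)]

    def test_escalation_prunes_mid_range_calls(self):
        out = escalate_cutoff(self._records([1.6, 1.9, 2.4]), 2.0)
        kept = [r.gene for r in out if r.direction is Direction.UNDER_IN_ALT]
        assert kept == ["Gene02"]

    def test_same_cutoff_is_identity(self):
        records = self._records([1.6, 1.9, 2.4])
        assert [r.direction for r in escalate_cutoff(records, 1.5)] == \
               [r.direction for r in records]

    def test_subset_property_on_random_records(self):
        rng = np.random.default_rng(5)
        fcs = np.exp(rng.normal(0, 1, size=200))
        records = self._records(fcs, cutoff=1.2)
        before = {r.gene for r in records if r.direction is not Direction.UNCHANGED}
        after = {r.gene for r in escalate_cutoff(records, 2.0)
                 if r.direction is not Direction.UNCHANGED}
        assert after <= before

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            escalate_cutoff(self._records([2.0]), 0.9)
        with pytest.raises(ValueError, match="below the cutoff already applied"):
            escalate_cutoff(self._records([2.0], cutoff=2.0), 1.5)


class TestTMM:
    def test_pure_depth_difference_gives_unit_factors(self):
        """One library exactly double the other: all M-values are zero."""
        a = np.array([100, 200, 300, 50, 75])
        m = make_matrix({"A": a, "B": 2 * a},
                        {"A": "x", "B": "y"}, unit="counts")
        factors = tmm_normalize(m).factors
        assert factors.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_identical_samples(self):
        a = [10, 20, 30]
        m = make_matrix({"A": a, "B": a}, {"A": "x", "B": "y"}, unit="counts")
        assert tmm_normalize(m).factors.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_three_gene_toy_matches_hand_oracle(self):
        """Frozen expectation computed independently (spreadsheet-style M/A/
        weight arithmetic, verified against edgeR::calcNormFactors)."""
        m = make_matrix({"A": [100, 200, 300], "B": [150, 900, 250]},
                        {"A": "x", "B": "y"}, unit="counts")
        factors = tmm_normalize(m, ref_sample="A").factors
        assert factors["A"] == pytest.approx(1.020400235963, abs=1e-9)
        assert factors["B"] == pytest.approx(0.980007613440, abs=1e-9)

    def test_eight_gene_toy_exercises_double_trim(self):
        """Frozen expectation computed independently with edgeR (trim active)."""
        m = make_matrix({"A": [500, 20, 1000, 75, 10, 350, 60, 2000],
                         "B": [400, 120, 900, 50, 35, 700, 40, 1800]},
                        {"A": "x", "B": "y"}, unit="counts")
        factors = tmm_normalize(m, ref_sample="A").factors
        assert factors["A"] == pytest.approx(1.025692362191, abs=1e-9)
        assert factors["B"] == pytest.approx(0.974951200634, abs=1e-9)

    def test_scaling_one_sample_leaves_factors_stable(self):
        """M-values are depth-invariant, so a pure depth change moves factors
        only through the (depth-dependent) precision weights — i.e. barely."""
        rng = np.random.default_rng(9)
        a = rng.poisson(50, size=200) + 1
        b = rng.poisson(50, size=200) + 1
        m1 = make_matrix({"A": a, "B": b}, {"A": "x", "B": "y"}, unit="counts")
        m2 = make_matrix({"A": a, "B": 7 * b}, {"A": "x", "B": "y"}, unit="counts")
        f1 = tmm_normalize(m1, ref_sample="A").factors
        f2 = tmm_normalize(m2, ref_sample="A").factors
        assert f1.to_numpy() == pytest.approx(f2.to_numpy(), rel=1e-2)

    def test_all_zero_sample_names_the_sample(self):
        m = make_matrix({"A": [1, 2], "B": [0, 0]}, {"A": "x", "B": "y"}, unit="counts")
        with pytest.raises(ValueError, match="'B'"):
            tmm_normalize(m)

    def test_requires_counts(self):
        m = make_matrix({"A": [1.5, 2.0], "B": [1.0, 1.0]}, {"A": "x", "B": "y"}, unit="FPKM")
        with pytest.raises(ValueError, match="counts"):
            tmm_normalize(m)


def _ko_matrix(rng, n_genes=400, planted=None, fc=6.0, mean=200.0, dispersion=0.01):
    """3 vs 3 NB count matrix with optional planted knockdowns."""
    base = rng.lognormal(math.log(mean), 0.6, size=n_genes)
    mu_ko = base.copy()
    if planted:
        mu_ko[list(planted)] = base[list(planted)] / fc
    size = 1.0 / dispersion
    cols = {}
    for j in range(3):
        cols[f"W{j}"] = rng.negative_binomial(size, size / (size + base))
    for j in range(3):
        cols[f"K{j}"] = rng.negative_binomial(size, size / (size + mu_ko))
    groups = {c: ("wt" if c.startswith("W") else "ko") for c in cols}
    return make_matrix(cols, groups, unit="counts")


class TestKnockoutTest:
    def test_planted_sixfold_shift_is_detected(self):
        """Strong planted knockdowns reach adjusted significance at n=3+3."""
        rng = np.random.default_rng(21)
        planted = list(range(10))
        m = _ko_matrix(rng, planted=planted)
        records = de_test_adjusted(m, "wt", "ko", alpha=0.05)
        flagged = {r.gene for r in records if r.p_adj < 0.05
                   and r.direction is Direction.UNDER_IN_ALT}
        planted_genes = {m.genes[i] for i in planted}
        assert len(planted_genes & flagged) >= 9  # >=90 % sensitivity

    def test_null_data_is_calibrated(self):
        """Identical groups: raw p roughly uniform, (almost) nothing after BH."""
        rng = np.random.default_rng(22)
        m = _ko_matrix(rng, n_genes=2000, planted=None)
        records = de_test_adjusted(m, "wt", "ko", alpha=0.05)
        raw = np.array([r.p_value for r in records])
        assert 0.01 < np.mean(raw < 0.05) < 0.12
        assert sum(r.p_adj < 0.05 for r in records) <= 2

    def test_welch_method_available(self):
        rng = np.random.default_rng(23)
        m = _ko_matrix(rng, n_genes=50, planted=[0], fc=30.0)
        records = de_test_adjusted(m, "wt", "ko", method="welch")
        assert all(r.p_value is not None for r in records)

    def test_constant_gene_not_significant(self):
        m = make_matrix({c: [5, 7] for c in ("W1", "W2", "K1", "K2")},
                        {"W1": "wt", "W2": "wt", "K1": "ko", "K2": "ko"},
                        unit="counts")
        records = de_test_adjusted(m, "wt", "ko")
        assert all(r.p_adj == 1.0 for r in records)

    def test_bh_preserves_raw_p_ordering(self):
        rng = np.random.default_rng(24)
        m = _ko_matrix(rng, n_genes=300, planted=list(range(5)))
        records = de_test_adjusted(m, "wt", "ko")
        by_raw = sorted(records, key=lambda r: r.p_value)
        adj = [r.p_adj for r in by_raw]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(r.p_adj >= r.p_value for r in records)

    def test_requires_replicates(self):
        m = make_matrix({"W1": [1, 2], "K1": [1, 2], "K2": [2, 3]},
                        {"W1": "wt", "K1": "ko", "K2": "ko"}, unit="counts")
        with pytest.raises(ValueError, match="two replicates"):
            de_test_adjusted(m, "wt", "ko")


class TestStandardCurve:
    def test_quantity_inversion(self):
        curve = fit_standard_curve([0.0, 10.0], [20.0, -13.0])
        assert curve.slope == pytest.approx(-3.3)
        assert ct_to_quantity(20.0, curve) == pytest.approx(0.0)

    def test_exact_line_recovery(self):
        amounts = [3.0 / 4**k for k in range(5)]  # five 1:4 dilutions
        cts = [20.0 - 3.3 * a for a in amounts]
        curve = fit_standard_curve(amounts, cts)
        assert curve.slope == pytest.approx(-3.3, rel=1e-12)
        assert curve.intercept == pytest.approx(20.0, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_replicates_averaged_before_fit(self):
        """Duplicate wells: fit must match OLS on the per-point means."""
        amounts = [1.0, 1.0, 4.0, 4.0]
        cts = [30.0, 31.0, 25.0, 26.0]
        curve = fit_standard_curve(amounts, cts)
        # closed-form OLS on the averaged points (30.5 @ 1, 25.5 @ 4)
        assert curve.slope == pytest.approx((25.5 - 30.5) / 3.0)

    def test_noisy_dilution_series_recovers_slope(self):
        rng = np.random.default_rng(31)
        amounts = np.array([3.0 / 4**k for k in range(5)])
        x = np.log10(amounts)
        cts = 18.0 - 3.4 * x + rng.normal(0, 0.05, size=5)
        curve = fit_standard_curve(amounts, cts, axis="log")
        # independent closed-form OLS oracle
        xc = x - x.mean()
        slope = float(np.sum(xc * (cts - cts.mean())) / np.sum(xc**2))
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.slope == pytest.approx(-3.4, abs=0.15)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([1.0, 1.0], [20.0, 21.0])
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestQpcrConcordance:
    def _records(self, fcs):
        return [DERecord(gene=g, mean_ref=1, mean_alt=1, fc=f,
                         direction=Direction.UNCHANGED) for g, f in fcs.items()]

    def test_identical_tables_agree_fully(self):
        fcs = {"Gene1": 2.0, "Gene2": 0.5, "Gene3": 3.3}
        frac, table = qpcr_concordance(self._records(fcs), fcs)
        assert frac == 1.0 and table["agree"].all()

    def test_opposite_signs_agree_never(self):
        fcs = {"Gene1": 2.0, "Gene2": 0.5}
        flipped = {g: 1.0 / f for g, f in fcs.items()}
        frac, _ = qpcr_concordance(self._records(fcs), flipped)
        assert frac == 0.0

    def test_matches_brute_force_sign_comparison(self):
        rng = np.random.default_rng(41)
        genes = [f"Gene{i}" for i in range(50)]
        rna = {g: float(np.exp(rng.normal(0, 1))) for g in genes}
        qpcr = {g: float(rna[g] * np.exp(rng.normal(0, 0.6))) for g in genes}
        frac, _ = qpcr_concordance(self._records(rna), qpcr)
        brute = np.mean([
            (math.log(rna[g]) > 0) == (math.log(qpcr[g]) > 0)
            or np.sign(math.log(rna[g])) == np.sign(math.log(qpcr[g]))
            for g in genes
        ])
        assert frac == pytest.approx(brute)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="shared"):
            qpcr_concordance(self._records({"Genea": 2.0}), {"Geneb": 2.0})
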