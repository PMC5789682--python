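"""Differential expression and qPCR quantification for the gonadal
transcriptome comparisons.

Two DE analyses are provided, matching the two designs they serve:

* :func:`fold_change_de` — ratio-of-group-means classification on an FPKM
  matrix (pooled-sample designs without replicates), with a configurable
  fold-change cutoff (1.5 by default, escalatable to 2 via
  :func:`escalate_cutoff`).  A record is ``under_in_alt`` when the
  reference/alternate ratio meets the cutoff, ``over_in_alt`` when its
  reciprocal does.
* :func:`de_test_adjusted` — replicate-based testing on integer counts
  (wild-type vs knockout, n >= 2 per group): TMM normalization, log2
  counts-per-million, a per-gene two-sample test with empirical-Bayes
  variance moderation by default (plain Welch available), and
  Benjamini-Hochberg adjustment.

TMM (trimmed mean of M-values) between-sample normalization is implemented
here following the published estimator: gene-wise log-ratios (M) and mean
log-abundances (A) against a reference sample are double-trimmed (30 % on
M, 5 % on A) and combined with inverse delta-method-variance weights;
factors are re-centered to geometric mean 1.

qPCR support covers standard-curve fitting (Ct = m*x + b over a dilution
series, replicates averaged per point) and Ct-to-quantity inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .tables_io import ExpressionMatrix

__all__ = [
    "Direction",
    "DERecord",
    "TMMFactors",
    "StandardCurve",
    "fold_change_de",
    "escalate_cutoff",
    "classify_direction",
    "tmm_normalize",
    "cpm",
    "de_test_adjusted",
    "fit_standard_curve",
    "ct_to_quantity",
    "qpcr_concordance",
    "de_records_to_frame",
]


class Direction(str, Enum):
    UNDER_IN_ALT = "under_in_alt"
    OVER_IN_ALT = "over_in_alt"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression result.

    ``fc`` is the (pseudocounted) reference/alternate ratio of group means,
    so ``fc > 1`` means lower expression in the alternate group.  ``fc`` is
    ``inf`` when the alternate mean is exactly zero with a zero pseudocount
    and ``nan`` (direction ``unchanged``) when both means are zero — the
    undefined case.  ``p_adj`` is only present for replicate-based tests.
    ``cutoff_used`` records the fold-change cutoff behind ``direction``
    (1.0 for sign-only classification in replicate-based tests).
    """

    gene: str
    mean_ref: float
    mean_alt: float
    fc: float
    direction: Direction
    p_adj: float | None = None
    p_value: float | None = None
    cutoff_used: float = 1.5

    @property
    def fc_defined(self) -> bool:
        return not math.isnan(self.fc)


def classify_direction(fc: float, cutoff: float) -> Direction:
    if not cutoff >= 1.0:
        raise ValueError("fold-change cutoff must be >= 1")
    if math.isnan(fc):
        return Direction.UNCHANGED
    if fc >= cutoff:
        return Direction.UNDER_IN_ALT
    if fc <= 1.0 / cutoff:
        return Direction.OVER_IN_ALT
    return Direction.UNCHANGED


def _group_means(matrix: ExpressionMatrix, group: str) -> np.ndarray:
    samples = matrix.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples in the matrix")
    return matrix.values[samples].to_numpy(float).mean(axis=1)


def fold_change_de(
    matrix: ExpressionMatrix,
    ref_group: str,
    alt_group: str,
    fc_cutoff: float = 1.5,
    pseudocount: float = 0.1,
) -> list[DERecord]:
    """Classify every gene by the fold change of group means.

    ``fc = (mean_ref + pseudocount) / (mean_alt + pseudocount)``.  The
    default pseudocount of 0.1 FPKM keeps ratios finite for genes silent in
    one group while leaving moderately expressed genes essentially
    untouched.
    """
    if not fc_cutoff > 1.0:
        raise ValueError("fc_cutoff must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_ref = _group_means(matrix, ref_group)
    mean_alt = _group_means(matrix, alt_group)
    num = mean_ref + pseudocount
    den = mean_alt + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(den > 0, num / den, np.where(num > 0, np.inf, np.nan))
    return [
        DERecord(
            gene=g,
            mean_ref=float(mr),
            mean_alt=float(ma),
            fc=float(f),
            direction=classify_direction(float(f), fc_cutoff),
            cutoff_used=fc_cutoff,
        )
        for g, mr, ma, f in zip(matrix.genes, mean_ref, mean_alt, fc)
    ]


def escalate_cutoff(de_records: Iterable[DERecord], new_cutoff: float) -> list[DERecord]:
    """Re-classify records under a stricter fold-change cutoff.

    The non-unchanged set under the new cutoff is always a subset of the
    original non-unchanged set.
    """
    records = list(de_records)
    if not new_cutoff >= 1.0:
        raise ValueError("new_cutoff must be >= 1")
    too_low = [r for r in records if new_cutoff < r.cutoff_used]
    if too_low:
        raise ValueError(
            f"new_cutoff {new_cutoff} is below the cutoff already applied "
            f"({too_low[0].cutoff_used})"
        )
    return [
        replace(r, direction=classify_direction(r.fc, new_cutoff), cutoff_used=new_cutoff)
        for r in records
    ]


# ---------------------------------------------------------------------------
# TMM normalization


@dataclass(frozen=True)
class TMMFactors:
    """Per-sample TMM normalization factors, re-centered to geometric mean 1.

    The effective library size of a sample is ``library_size * factor``.
    """

    factors: pd.Series
    ref_sample: str
    trim_m: float
    trim_a: float

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def _pairwise_tmm(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method variance of M for binomial counts; weights are 1/variance
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any():
        return 1.0
    f = np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    return float(2.0 ** f)


def tmm_normalize(
    matrix: ExpressionMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> TMMFactors:
    """Estimate TMM normalization factors from an integer-count matrix.

    When ``ref_sample`` is not given, the sample whose 75th count-fraction
    percentile is closest to the mean across samples is used as reference.
    Genes with a zero count in either member of a pair are excluded from
    that pair's trimmed mean.
    """
    if matrix.unit != "counts":
        raise ValueError("TMM normalization requires a counts matrix")
    if len(matrix.samples) < 2:
        raise ValueError("TMM normalization needs at least two samples")
    counts = matrix.values.to_numpy(float)
    lib = counts.sum(axis=0)
    for sample, total in zip(matrix.samples, lib):
        if total == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(len(lib))])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        ref_sample = matrix.samples[ref_idx]
    else:
        if ref_sample not in matrix.samples:
            raise ValueError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = matrix.samples.index(ref_sample)
    raw = np.array(
        [
            _pairwise_tmm(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(len(lib))
        ]
    )
    centered = raw / np.exp(np.mean(np.log(raw)))
    return TMMFactors(
        factors=pd.Series(centered, index=matrix.samples, name="tmm_factor"),
        ref_sample=ref_sample,
        trim_m=trim_m,
        trim_a=trim_a,
    )


def cpm(
    matrix: ExpressionMatrix,
    factors: TMMFactors | None = None,
    log2: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over TMM-effective library sizes."""
    counts = matrix.values.to_numpy(float)
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors.factors.reindex(matrix.samples).to_numpy()
    out = counts / lib * 1e6
    if log2:
        out = np.log2(out + prior)
    return pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)


# ---------------------------------------------------------------------------
# replicate-based DE testing (wild-type vs knockout)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes (prior df, prior variance) for per-gene variances.

    Method-of-moments fit of a scaled F distribution to the observed
    variances via the log-variance mean and spread; returns
    ``(d0, s0_squared)`` with ``d0 = inf`` when the variances are
    essentially constant.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        return math.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(resid)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s02


def de_test_adjusted(
    matrix: ExpressionMatrix,
    ref_group: str,
    alt_group: str,
    alpha: float = 0.05,
    method: str = "moderated",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> list[DERecord]:
    """Per-gene two-sample DE test on TMM-normalized log2 CPM.

    ``method="moderated"`` (default) shrinks per-gene variances toward a
    common prior before forming the t statistic — the standard remedy for
    tiny-replicate designs, where raw per-gene variances are too noisy for
    an unmoderated test to retain power after multiple-testing correction.
    ``method="welch"`` is the plain unequal-variance t test.  P values are
    Benjamini-Hochberg adjusted across all tested genes; a gene is
    significant when ``p_adj < alpha``.  Direction is sign-based
    (``cutoff_used = 1``): ``under_in_alt`` whenever the alternate-group
    mean is lower.
    """
    ref_samples = matrix.samples_in(ref_group)
    alt_samples = matrix.samples_in(alt_group)
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError("each group needs at least two replicates")
    factors = tmm_normalize(matrix, trim_m=trim_m, trim_a=trim_a)
    log_cpm = cpm(matrix, factors, log2=True)
    y1 = log_cpm[ref_samples].to_numpy()
    y2 = log_cpm[alt_samples].to_numpy()
    n1, n2 = y1.shape[1], y2.shape[1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    diff = m1 - m2

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(y1, y2, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # zero-variance genes: undefined -> not significant
    elif method == "moderated":
        v1 = y1.var(axis=1, ddof=1)
        v2 = y2.var(axis=1, ddof=1)
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        d0, s02 = _squeeze_var(s2, df_resid)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = 1e9
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = np.ones_like(diff)
        nonzero = se > 0
        t = np.zeros_like(diff)
        t[nonzero] = diff[nonzero] / se[nonzero]
        p[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), df_total)
        # zero moderated variance with a nonzero difference: maximally significant
        p[(~nonzero) & (diff != 0)] = np.finfo(float).tiny
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    mean_ref_cpm = (2.0 ** y1 - 0.5).clip(min=0).mean(axis=1)
    mean_alt_cpm = (2.0 ** y2 - 0.5).clip(min=0).mean(axis=1)
    fc = 2.0 ** diff
    return [
        DERecord(
            gene=g,
            mean_ref=float(mr),
            mean_alt=float(ma),
            fc=float(f),
            direction=classify_direction(float(f), 1.0) if f != 1.0 else Direction.UNCHANGED,
            p_adj=float(pa),
            p_value=float(pv),
            cutoff_used=1.0,
        )
        for g, mr, ma, f, pa, pv in zip(matrix.genes, mean_ref_cpm, mean_alt_cpm, fc, p_adj, p)
    ]


# ---------------------------------------------------------------------------
# qPCR standard curves


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = slope * x + intercept over a dilution series.

    ``axis`` records whether x is the cDNA amount itself (``"linear"``,
    the default) or its log10 (``"log"``).
    """

    slope: float
    intercept: float
    r_squared: float
    axis: str = "linear"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be nonzero")


def fit_standard_curve(
    amounts: Sequence[float],
    cts: Sequence[float],
    axis: str = "linear",
) -> StandardCurve:
    """Ordinary least squares of Ct on cDNA amount.

    Replicate Ct values at the same input amount are averaged before the
    fit (the usual duplicate-well protocol).  ``axis="log"`` fits against
    log10(amount) instead — the common choice for serial-dilution series.
    """
    if axis not in ("linear", "log"):
        raise ValueError("axis must be 'linear' or 'log'")
    df = pd.DataFrame({"x": np.asarray(amounts, float), "ct": np.asarray(cts, float)})
    if df.isna().to_numpy().any():
        raise ValueError("amounts and Ct values must be finite")
    averaged = df.groupby("x", sort=True)["ct"].mean()
    if len(averaged) < 2:
        raise ValueError("need at least two distinct dilution points")
    x = averaged.index.to_numpy(float)
    if axis == "log":
        if (x <= 0).any():
            raise ValueError("log axis requires positive amounts")
        x = np.log10(x)
    y = averaged.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("dilution points are not distinct on the fitted axis")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValueError("degenerate fit: zero slope")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2), axis=axis)


def ct_to_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: x = (Ct - intercept) / slope.

    The value is on the fitted axis — log10 cDNA amount when the curve was
    fitted with ``axis="log"``.
    """
    return (ct - curve.intercept) / curve.slope


def qpcr_concordance(
    de_records: Iterable[DERecord],
    qpcr_fc: Mapping[str, float],
) -> tuple[float, pd.DataFrame]:
    """Direction agreement between sequencing and qPCR fold changes.

    Both inputs are ratio-scale fold changes (reference over alternate).
    Returns the fraction of shared genes whose log fold changes agree in
    sign, plus a per-gene table.
    """
    rna = {r.gene: r.fc for r in de_records}
    shared = sorted(set(rna) & set(qpcr_fc))
    if not shared:
        raise ValueError("no genes shared between the DE records and the qPCR table")
    rows = []
    for g in shared:
        sign_rna = np.sign(np.log(rna[g])) if rna[g] > 0 else np.nan
        sign_q = np.sign(np.log(qpcr_fc[g])) if qpcr_fc[g] > 0 else np.nan
        rows.append(
            {
                "gene": g,
                "fc_rnaseq": rna[g],
                "fc_qpcr": qpcr_fc[g],
                "agree": bool(sign_rna == sign_q),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return float(table["agree"].mean()), table


def de_records_to_frame(records: Iterable[DERecord]) -> pd.DataFrame:
    """Tabulate DE records (gene, means, fc, direction, p values)."""
    rows = list(records)
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "mean_ref": [r.mean_ref for r in rows],
            "mean_alt": [r.mean_alt for r in rows],
            "fc": [r.fc for r in rows],
            "direction": [r.direction.value for r in rows],
            "p_value": [r.p_value for r in rows],
            "p_adj": [r.p_adj for r in rows],
        }
    )
    return df.set_index("gene")
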