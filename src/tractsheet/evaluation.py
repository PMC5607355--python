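"""Evaluation metrics: Dice overlap, Bhattacharyya distances, Wilcoxon tests.

These are the quantitative tools for judging a skeleton-projection pipeline
against native-space tractography: pairwise Dice scores measure how well a
registration aligns subjects' tracts; the Bhattacharyya distance between
normalized FA histograms measures how far a projected FA distribution drifts
from the native-space one; the Wilcoxon signed-rank test compares paired
per-subject scores between two methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import BinaryMask, Histogram, ValidationError


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two masks on a common grid."""
    if not a.same_grid(b):
        raise ValidationError("masks are not on a common grid")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        raise ValidationError("both masks are empty")
    inter = int(np.sum(a.values & b.values))
    return 2.0 * inter / (na + nb)


def pairwise_median_dice(masks: list[BinaryMask]) -> np.ndarray:
    """Per-subject median of Dice scores against all other subjects."""
    n = len(masks)
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    d = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dice(masks[i], masks[j])
    return np.array([np.nanmedian(d[i]) for i in range(n)])


def fa_histogram(values, n_bins: int = 100, range_: tuple[float, float] = (0.0, 1.0)) -> Histogram:
    """Normalized equal-width histogram of FA values; out-of-range values are
    clipped with a warning."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValidationError("cannot histogram an empty value set")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = range_
    if np.any(vals < lo) or np.any(vals > hi):
        warnings.warn("values outside histogram range were clipped", stacklevel=2)
        vals = np.clip(vals, lo, hi)
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, probs=counts / counts.sum())


def bhattacharyya_distance(p: Histogram, q: Histogram) -> float:
    """D_B = -ln sum_i sqrt(p_i q_i); 0 iff the histograms are identical."""
    if len(p.probs) != len(q.probs) or not np.allclose(p.bin_edges, q.bin_edges):
        raise ValidationError("histograms must share identical bin edges")
    bc = float(np.sum(np.sqrt(p.probs * q.probs)))
    if bc <= 0.0:
        warnings.warn("disjoint histogram supports; Bhattacharyya distance infinite",
                      stacklevel=2)
        return float("inf")
    return float(-np.log(min(bc, 1.0)))


def _exact_signed_rank_tail(ranks2: np.ndarray, w2: int):
    """Null counts of the doubled signed-rank statistic by dynamic programming.

    ``ranks2`` are the doubled midranks (integers).  Returns
    (P(W2 <= w2), P(W2 >= w2)) under random independent signs.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] = counts[r:] + counts[:total + 1 - r]
    denom = counts.sum()
    le = counts[: w2 + 1].sum() / denom
    ge = counts[w2:].sum() / denom
    return le, ge


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float
    n_used: int
    n_zeros_dropped: int
    method: str

    def __float__(self) -> float:
        return self.p_value


def wilcoxon_signed_rank(paired_diffs, alternative: str = "two_sided",
                         exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (their count is reported).  For n up to
    ``exact_max_n`` the null is enumerated exactly over all sign assignments
    (midranks handled by doubling, so ties are exact too); beyond that a
    normal approximation with tie and continuity corrections is used.
    ``alternative`` is ``two_sided``, ``greater`` (positive shift) or ``less``.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValidationError("alternative must be two_sided, greater or less")
    d = np.asarray(paired_diffs, dtype=float).ravel()
    nz = d[d != 0.0]
    n_zeros = d.size - nz.size
    if nz.size == 0:
        raise ValidationError("all paired differences are zero")
    if nz.size < 5:
        warnings.warn(f"only {nz.size} nonzero differences; test has little power",
                      stacklevel=2)
    n = nz.size
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(np.rint(2 * w_plus))
        le, ge = _exact_signed_rank_tail(ranks2, w2)
        if alternative == "greater":
            p = ge
        elif alternative == "less":
            p = le
        else:
            p = min(1.0, 2.0 * min(le, ge))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            p = sps.norm.sf((w_plus - mean - 0.5) / sd)
        elif alternative == "less":
            p = sps.norm.cdf((w_plus - mean + 0.5) / sd)
        else:
            z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / sd
            p = 2.0 * sps.norm.sf(abs(z))
        p = float(min(1.0, p))
        method = "normal_approx"
    return WilcoxonResult(p_value=float(p), statistic=w_plus, n_used=n,
                          n_zeros_dropped=n_zeros, method=method)


def compare_projection_methods(native_values: list, tsa_values: list,
                               tbss_values: list, n_bins: int = 100):
    """Per-subject comparison of projected FA against native-space tractography.

    For every subject this reports the mean FA under each method and the
    Bhattacharyya distance from the native-space FA distribution to the
    medial-surface (TSA) and to the TBSS-style projections; cohort-level
    paired Wilcoxon tests compare the methods.

    Returns ``(report, tests)``: a DataFrame with one row per subject and a
    dict of WilcoxonResult for each paired contrast.
    """
    if not (len(native_values) == len(tsa_values) == len(tbss_values)):
        raise ValidationError("need one value set per subject for every method")
    rows = []
    for i, (nat, tsa, tb) in enumerate(zip(native_values, tsa_values, tbss_values)):
        nat, tsa, tb = (np.asarray(x, float).ravel() for x in (nat, tsa, tb))
        if min(nat.size, tsa.size, tb.size) == 0:
            raise ValidationError(f"subject {i}: empty value set")
        h_nat = fa_histogram(nat, n_bins)
        rows.append({
            "subject": i,
            "mean_native": nat.mean(),
            "mean_tsa": tsa.mean(),
            "mean_tbss": tb.mean(),
            "db_native_tsa": bhattacharyya_distance(h_nat, fa_histogram(tsa, n_bins)),
            "db_native_tbss": bhattacharyya_distance(h_nat, fa_histogram(tb, n_bins)),
            "n_bins": n_bins,
        })
    report = pd.DataFrame(rows)

    def safe(diffs, **kw):
        d = np.asarray(diffs, float)
        if np.all(d == 0.0):  # identical methods: no evidence of a difference
            return WilcoxonResult(p_value=1.0, statistic=0.0, n_used=0,
                                  n_zeros_dropped=d.size, method="degenerate")
        return wilcoxon_signed_rank(d, **kw)

    tests = {
        "mean_tsa_vs_native": safe(report["mean_tsa"] - report["mean_native"]),
        "mean_tbss_vs_native": safe(report["mean_tbss"] - report["mean_native"]),
        "mean_tbss_vs_tsa_greater": safe(
            report["mean_tbss"] - report["mean_tsa"], alternative="greater"),
        "db_tbss_vs_tsa_greater": safe(
            report["db_native_tbss"] - report["db_native_tsa"], alternative="greater"),
    }
    return report, tests


__all__ = [
    "dice", "pairwise_median_dice", "fa_histogram", "bhattacharyya_distance",
    "wilcoxon_signed_rank", "WilcoxonResult", "compare_projection_methods",
]
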