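"""Inferential statistics for population and group comparisons.

Contracts chosen so that reported population statistics are reproducible from
counts: the chi-square is the Pearson statistic without continuity
correction; Fisher's test is the exact two-tailed hypergeometric sum;
Mann-Whitney and Wilcoxon use exact enumeration at small n and tie-corrected
normal approximations (no continuity correction) beyond.  All p-values are
two-tailed.  Bonferroni correction is available as an explicit helper and
is never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .isi_latency import latency_correlation as pearson_r  # noqa: F401  (re-export)

#: exact-enumeration cutoffs
MANN_WHITNEY_EXACT_N = 12      # per group
WILCOXON_EXACT_N = 15          # nonzero pairs


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: int | None = None


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return t


def chi_square(table) -> TestResult:
    """Pearson chi-square without continuity correction.

    df = (r−1)(c−1); a zero row/column marginal is an error naming the
    degenerate margin.
    """
    t = _as_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any():
        raise ValueError(f"zero marginal in row {int(np.nonzero(rows == 0)[0][0])}")
    if (cols == 0).any():
        raise ValueError(f"zero marginal in column {int(np.nonzero(cols == 0)[0][0])}")
    res = sps.chi2_contingency(t, correction=False)
    return TestResult(float(res.statistic), float(res.pvalue), int(res.dof))


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p: the sum of probabilities of all tables
    with the observed margins no more probable than the observed one."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact requires a 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# rank tests


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _two_sided_from_cdf(p_le: float, p_ge: float) -> float:
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(a, b) -> TestResult:
    """Mann-Whitney U (U of the first sample) with two-tailed p.

    Exact for ≤ 12 observations per group — by the exact U distribution
    when the pooled sample is tie-free, by full enumeration of group
    assignments with midranks otherwise; tie-corrected normal
    approximation (no continuity correction) for larger samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    if max(n1, n2) <= MANN_WHITNEY_EXACT_N:
        if not has_ties:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return TestResult(float(res.statistic), float(res.pvalue))
        # enumeration with midranks: U for every assignment of n1 ranks
        us = np.array([sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0
                       for c in combinations(range(n1 + n2), n1)])
        eps = 1e-9
        p = _two_sided_from_cdf(float(np.mean(us <= u1 + eps)),
                                float(np.mean(us >= u1 - eps)))
        return TestResult(u1, p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return TestResult(float(res.statistic), float(res.pvalue))


def wilcoxon_signed_rank(diffs) -> TestResult:
    """Wilcoxon signed-rank on paired differences, two-tailed.

    Zero differences are dropped; with none remaining the test abstains
    (NaN statistic and p).  Exact sign enumeration (midranks on |d|) for
    ≤ 15 nonzero pairs; tie-corrected normal approximation (no continuity
    correction) beyond.  The statistic is W = min(W+, W−).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(np.nan, np.nan)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_N:
        if np.unique(np.abs(d)).size == n:
            res = sps.wilcoxon(d, alternative="two-sided", method="exact")
            return TestResult(float(res.statistic), float(res.pvalue))
        # midrank ties: enumerate all 2^n sign assignments of the ranks
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
        wp = signs @ ranks
        eps = 1e-9
        p = _two_sided_from_cdf(float(np.mean(wp <= w_plus + eps)),
                                float(np.mean(wp >= w_plus - eps)))
        return TestResult(w, p)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                       alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue))


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni-adjusted p-values (capped at 1) and the adjusted alpha.

    Exposed as an explicit step; nothing in the package applies it
    implicitly.
    """
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0), alpha / max(p.size, 1)


# ---------------------------------------------------------------------------
# laser (optrode) modulation


@dataclass(frozen=True)
class LaserModulation:
    """Per-unit ON/OFF firing comparison under an optrode protocol."""

    direction: str            # 'increase' | 'decrease' | 'none'
    p: float
    off_rate_hz: float
    on_rate_hz: float
    n_bins: int


def classify_laser_modulation(spike_times_s, laser_intervals_s,
                              protocol=None, alpha: float = 0.05,
                              bin_s: float = 1.0) -> LaserModulation:
    """Classify a unit's laser response: Wilcoxon signed-rank on paired
    1-s bin rates, OFF window immediately preceding each ON interval.

    For each laser ON interval of duration L, spikes are counted in 1-s
    bins over [on−L, on) (OFF) and [on, on+L) (ON), rates averaged across
    trials per bin index, and the OFF/ON bin pairs compared.  p < alpha
    calls the direction by the mean rate difference; otherwise 'none'.
    """
    t = np.asarray(spike_times_s, dtype=float)
    intervals = [(float(a), float(b)) for a, b in laser_intervals_s]
    if not intervals:
        raise ValueError("no laser intervals supplied")
    L = intervals[0][1] - intervals[0][0]
    if any(abs((b - a) - L) > 1e-9 for a, b in intervals):
        raise ValueError("laser ON intervals must share one duration")
    if protocol is not None:
        if abs(L - protocol.on_s) > 1e-9:
            raise ValueError(
                f"ON duration {L} s does not match protocol {protocol.name!r}")
        if len(intervals) < protocol.n_trials:
            raise ValueError(
                f"protocol {protocol.name!r} expects ≥{protocol.n_trials} trials")
    nb = int(round(L / bin_s))
    off = np.zeros((len(intervals), nb))
    on = np.zeros((len(intervals), nb))
    for i, (a, _) in enumerate(intervals):
        off_edges = a - L + np.arange(nb + 1) * bin_s
        on_edges = a + np.arange(nb + 1) * bin_s
        off[i] = np.diff(np.searchsorted(t, off_edges)) / bin_s
        on[i] = np.diff(np.searchsorted(t, on_edges)) / bin_s
    off_mean = off.mean(axis=0)
    on_mean = on.mean(axis=0)
    res = wilcoxon_signed_rank(on_mean - off_mean)
    direction = "none"
    if np.isfinite(res.p) and res.p < alpha:
        direction = "increase" if on_mean.mean() > off_mean.mean() else "decrease"
    return LaserModulation(direction=direction, p=float(res.p),
                           off_rate_hz=float(off_mean.mean()),
                           on_rate_hz=float(on_mean.mean()), n_bins=nb)


__all__ = [
    "TestResult", "chi_square", "fisher_exact_2x2", "mann_whitney_u",
    "wilcoxon_signed_rank", "bonferroni", "pearson_r",
    "LaserModulation", "classify_laser_modulation",
    "MANN_WHITNEY_EXACT_N", "WILCOXON_EXACT_N",
]
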