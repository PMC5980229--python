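"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most literal route available
(per-spike loops, full enumeration, fine discretization), sharing no code
with the package paths it checks.
"""

import itertools
import math
import statistics


def brute_bin_counts(spikes, align_time, edges, cut=math.inf):
    """Per-spike assignment to half-open bins, truncated at ``cut``."""
    counts = [0] * (len(edges) - 1)
    for s in spikes:
        rel = s - align_time
        for i in range(len(edges) - 1):
            lo, hi = edges[i], min(edges[i + 1], cut - align_time)
            if lo <= rel < hi:
                counts[i] += 1
    return counts


def brute_fisher_p(table):
    """Two-tailed Fisher exact p by enumerating all tables with the
    observed margins, summing probabilities ≤ the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # hypergeometric pmf of the top-left cell
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_mann_whitney(a, b):
    """(U of sample a, two-tailed p) by enumerating group assignments."""
    n1 = len(a)
    pooled = list(a) + list(b)
    ranks = _midranks(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = [sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
          for combo in itertools.combinations(range(len(pooled)), n1)]
    eps = 1e-9
    p_le = sum(u <= u_obs + eps for u in us) / len(us)
    p_ge = sum(u >= u_obs - eps for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def brute_wilcoxon(diffs):
    """(W = min(W+, W−), two-tailed p) by enumerating all sign vectors."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = _midranks([abs(x) for x in d])
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    w_minus = sum(r for r, x in zip(ranks, d) if x < 0)
    wp = [sum(r for r, s in zip(ranks, signs) if s > 0)
          for signs in itertools.product([1, -1], repeat=n)]
    eps = 1e-9
    p_le = sum(w <= w_plus + eps for w in wp) / len(wp)
    p_ge = sum(w >= w_plus - eps for w in wp) / len(wp)
    return min(w_plus, w_minus), min(1.0, 2 * min(p_le, p_ge))


def brute_inhibition_latency(spikes, tone_onset, tone_s=30.0,
                             baseline_s=30.0, z_crit=1.65):
    """Literal scan: pretone ISI mean/SD via the statistics module, then the
    first tone-window ISI whose z exceeds the criterion."""
    spikes = list(spikes)
    pre = [t for t in spikes if tone_onset - baseline_s <= t < tone_onset]
    isis = [b - a for a, b in zip(pre, pre[1:])]
    if len(isis) < 2:
        return None
    mean = statistics.fmean(isis)
    sd = statistics.stdev(isis)
    if sd <= 0:
        return None
    for a, b in zip(spikes, spikes[1:]):
        if tone_onset <= a < tone_onset + tone_s:
            if (b - a - mean) / sd > z_crit:
                return a - tone_onset
    return None


def brute_interval_overlap(intervals, window, dt=0.001):
    """Occupancy of ``intervals ∩ window`` by 1-ms discretization."""
    lo, hi = window
    n = int(round((hi - lo) / dt))
    covered = 0
    for i in range(n):
        t = lo + (i + 0.5) * dt
        if any(a <= t < b for a, b in intervals):
            covered += 1
    return covered * dt


def brute_pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)
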