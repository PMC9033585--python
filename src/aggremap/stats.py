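"""Nonparametric group comparison for per-object morphometry.

Per-object measurements (aggresome areas, intensities, colocalization
coefficients) are compared across conditions with a Kruskal–Wallis omnibus
test on midranks with tie correction, followed by a Dunn post-hoc test for
pairwise differences (Bonferroni-adjusted two-sided p values). Replicate
percentages are compared with classical two-tailed unpaired Student
t-tests. Box/whisker summaries follow the convention: median, quartiles,
whiskers at the most extreme points within 1.5×IQR of the box.

Quantiles everywhere are linear-interpolation quantiles between order
statistics, matching the lower-quartile background subtraction so one
definition serves the whole package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass
class DunnResult:
    pair: tuple                 # (group_a, group_b)
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupStats:
    groups: dict                # condition -> np.ndarray
    kw_H: float
    kw_p: float
    dunn: list                  # of DunnResult
    boxplot: dict               # condition -> BoxplotSummary


def _ranks_and_ties(groups: dict):
    names = list(groups)
    vecs = [np.asarray(groups[k], dtype=float) for k in names]
    if len(vecs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in vecs):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(vecs)
    ranks = sps.rankdata(pooled)            # midranks
    sizes = [len(v) for v in vecs]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    _, counts = np.unique(pooled, return_counts=True)
    return names, split, sizes, counts, len(pooled)


def kruskal_wallis(groups: dict) -> tuple:
    """Kruskal–Wallis H on midranks with tie correction; chi-square p.

    H = [12/(N(N+1)) · Σ Rᵢ²/nᵢ − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)] with the
    sum over tie groups of size t; p from χ² with k−1 degrees of freedom.
    """
    names, split, sizes, counts, N = _ranks_and_ties(groups)
    H = 12.0 / (N * (N + 1)) * sum(
        r.sum() ** 2 / n for r, n in zip(split, sizes)) - 3.0 * (N + 1)
    tie = 1.0 - (counts ** 3 - counts).sum() / (N ** 3 - N)
    if tie == 0:                            # all values identical
        return 0.0, 1.0
    H /= tie
    p = float(sps.chi2.sf(H, df=len(names) - 1))
    return float(H), p


def dunn_posthoc(groups: dict, adjustment: str = "bonferroni") -> list:
    """Dunn pairwise z tests on the pooled midranks of all groups.

    z_ab = (R̄_a − R̄_b) / sqrt( [N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/n_a + 1/n_b) )

    Two-sided p values; ``adjustment`` is ``"bonferroni"`` (over all pairs)
    or ``"none"``.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    names, split, sizes, counts, N = _ranks_and_ties(groups)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    means = {k: r.mean() for k, r in zip(names, split)}
    ns = dict(zip(names, sizes))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / ns[a] + 1.0 / ns[b]))
        z = (means[a] - means[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjustment == "bonferroni" else p
        out.append(DunnResult((a, b), float(z), float(p), float(p_adj)))
    return out


def t_test_two_tailed(a, b) -> tuple:
    """Classical unpaired equal-variance t-test, two-sided.

    Pooled variance with n₁+n₂−2 degrees of freedom. Raises on vectors
    shorter than 2 or zero pooled variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
        / (len(a) + len(b) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    df = len(a) + len(b) - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles and 1.5×IQR whiskers clamped to the data range."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return BoxplotSummary(float(med), float(q1), float(q3),
                          float(lo), float(hi))


def compare_groups(groups: dict, adjustment: str = "bonferroni") -> GroupStats:
    """Full statistics bundle: KW omnibus, Dunn pairs, box summaries."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    H, p = kruskal_wallis(arrays)
    dunn = dunn_posthoc(arrays, adjustment)
    boxes = {k: boxplot_summary(v) for k, v in arrays.items()}
    return GroupStats(arrays, H, p, dunn, boxes)
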