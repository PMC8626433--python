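"""Statistical battery for grade discrimination.

Grouped descriptive summaries (mean +/- SD, median [q1; q3] with the
weighted-average quantile convention), nonparametric comparisons
(Kruskal-Wallis with Dunn-style post-hoc pairwise z tests, Mann-Whitney,
Wilcoxon signed rank — exact by enumeration at small n, tie-aware
throughout), and ROC analysis with the Youden-index optimal cutoff and its
operating-point metrics (sensitivity, specificity, PPV, NPV).

Exact two-sided p-values are defined symmetrically under the permutation
null: p = P(|T - E[T]| >= |t_obs - E[T]|), which is well defined with ties
and reduces to the familiar doubling for symmetric null distributions.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "RocResult",
    "OperatingPoint",
    "round_half_up",
    "summarize",
    "group_summary",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "roc_auc",
    "youden_cutoff",
    "operating_point",
    "roc_analysis",
]

_EPS = 1e-12


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed precision)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# descriptive summaries

@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float | None  # sample SD (n-1); undefined for n < 2
    median: float
    q1: float
    q3: float


def _quantile(sorted_vals: np.ndarray, p: float) -> float:
    """Weighted-average quantile at position (n+1)p with linear
    interpolation, clamped to the observed range at the edges."""
    n = len(sorted_vals)
    pos = (n + 1) * p
    if pos <= 1:
        return float(sorted_vals[0])
    if pos >= n:
        return float(sorted_vals[-1])
    lo = int(np.floor(pos)) - 1
    frac = pos - np.floor(pos)
    return float(sorted_vals[lo] + frac * (sorted_vals[lo + 1] - sorted_vals[lo]))


def summarize(values: Sequence[float]) -> GroupSummary:
    """Descriptive summary of one sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    s = np.sort(v)
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size >= 2 else None,
        median=_quantile(s, 0.5),
        q1=_quantile(s, 0.25),
        q3=_quantile(s, 0.75),
    )


def group_summary(values: Sequence[float], labels: Sequence[object]) -> dict[object, GroupSummary]:
    """Per-group descriptive summaries, keyed by group label."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if v.shape != lab.shape:
        raise ValueError("values and labels differ in length")
    out = {}
    for g in pd.unique(lab):
        grp = v[lab == g]
        if grp.size == 0:
            raise ValueError(f"group {g!r} is empty")
        out[g] = summarize(grp)
    return out


# --------------------------------------------------------------------------
# rank tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False
    details: dict = field(default_factory=dict)


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _kw_h(pooled: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for groups laid out contiguously."""
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for ni in sizes:
        h += ranks[start : start + ni].sum() ** 2 / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n**3 - n)
    if correction == 0:  # every observation identical
        return 0.0
    return h / correction


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray, groups: list) -> pd.DataFrame:
    """Rank-based pairwise z comparisons on the pooled ranking, tie-corrected,
    Bonferroni-adjusted over all group pairs."""
    n = len(values)
    ranks = sps.rankdata(values)
    tie = _tie_term(values)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        ra = ranks[labels == ga]
        rb = ranks[labels == gb]
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(
    values: Sequence[float],
    labels: Sequence[object],
    method: str = "auto",
    exact_n_max: int = 9,
) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups with post-hoc pairwise table.

    ``method``: ``"asymptotic"`` refers tie-corrected H to chi-square with
    k-1 df; ``"permutation"`` enumerates every assignment of the pooled
    observations to the group sizes (p = P(H >= H_obs)); ``"auto"`` uses the
    permutation route when the pooled sample has at most ``exact_n_max``
    observations.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    groups = list(pd.unique(lab))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[lab == g] for g in groups]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    n = v.size
    sizes = [s.size for s in samples]
    pooled = np.concatenate(samples)
    h_obs = _kw_h(pooled, sizes)

    if method == "auto":
        method = "permutation" if n <= exact_n_max else "asymptotic"
    if method == "asymptotic":
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
            h, p = float(h), float(p)
        label = "Kruskal-Wallis (asymptotic chi-square)"
    elif method == "permutation":
        count = total = 0
        for perm in _distinct_group_assignments(pooled, sizes):
            total += 1
            if _kw_h(perm, sizes) >= h_obs - _EPS:
                count += 1
        h, p = h_obs, count / total
        label = "Kruskal-Wallis (exact permutation)"
    else:
        raise ValueError(f"unknown method {method!r}")

    pairwise = _dunn_pairwise(v, lab, groups)
    return TestResult(h, p, label, pairwise=pairwise)


def _distinct_group_assignments(pooled: np.ndarray, sizes: Sequence[int]):
    """Yield each assignment of the pooled values to ordered groups of the
    given sizes once (multiset permutations via index combinations)."""
    n = len(pooled)

    def rec(remaining: tuple[int, ...], sizes_left: list[int], acc: list[np.ndarray]):
        if not sizes_left:
            yield np.concatenate(acc)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, sizes_left[1:], acc + [pooled[list(combo)]])

    yield from rec(tuple(range(n)), list(sizes), [])


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
    exact_n_max: int = 12,
) -> TestResult:
    """Mann-Whitney U test; U counts pairs where a > b, ties counting 1/2.

    Exact p by enumeration over all assignments of the pooled sample when
    n_a + n_b <= ``exact_n_max`` (method "auto"), otherwise a normal
    approximation with tie-corrected variance. The reported statistic is
    U for ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    if method == "auto":
        method = "exact" if n <= exact_n_max else "asymptotic"
    if method == "exact":
        count = total = 0
        for combo in itertools.combinations(range(n), na):
            u = float(ranks[list(combo)].sum() - na * (na + 1) / 2.0)
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - _EPS:
                count += 1
        p = count / total
        label = "Mann-Whitney (exact enumeration)"
    elif method == "asymptotic":
        tie = _tie_term(pooled)
        sigma2 = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (u_obs - mu) / np.sqrt(sigma2)
            p = float(2.0 * sps.norm.sf(abs(z)))
        label = "Mann-Whitney (normal approximation, tie-corrected)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(u_obs, min(1.0, p), label)


def wilcoxon_signed_rank(
    paired_before: Sequence[float],
    paired_after: Sequence[float],
    method: str = "auto",
    exact_n_max: int = 15,
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Differences ``after - before``; zero differences are dropped. The
    statistic is W+, the sum of midranks of positive differences. Exact p by
    enumerating all 2^n sign assignments when n <= ``exact_n_max``; the
    one-sided p (P(W+ <= w)) is exposed in ``details``.
    """
    before = np.asarray(paired_before, dtype=float)
    after = np.asarray(paired_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "Wilcoxon signed rank (degenerate: all pairs tied)",
                          degenerate=True)
    r = sps.rankdata(np.abs(d))
    w_obs = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if method == "auto":
        method = "exact" if n <= exact_n_max else "asymptotic"
    if method == "exact":
        count = count_le = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            w = float(sum(rk for s, rk in zip(signs, r) if s))
            if abs(w - mu) >= abs(w_obs - mu) - _EPS:
                count += 1
            if w <= w_obs + _EPS:
                count_le += 1
        p = count / total
        details = {"p_one_sided": count_le / total}
        label = "Wilcoxon signed rank (exact enumeration)"
    elif method == "asymptotic":
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie = float(np.sum(counts.astype(float) ** 3 - counts))
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
        z = (w_obs - mu) / np.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
        details = {"p_one_sided": float(sps.norm.cdf(z))}
        label = "Wilcoxon signed rank (normal approximation, tie-corrected)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(w_obs, min(1.0, p), label, details=details)


# --------------------------------------------------------------------------
# ROC / Youden

class OperatingPoint(NamedTuple):
    sensitivity: float
    specificity: float
    ppv: float | None  # None when no prediction of that kind exists
    npv: float | None


@dataclass(frozen=True)
class RocResult:
    """AUC plus the Youden-optimal cutoff and its operating point
    (percentages; classification rule: score >= cutoff => positive)."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    youden_j: float


def _split(scores: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape:
        raise ValueError("scores and labels differ in length")
    pos, neg = s[lab], s[~lab]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the empirical ROC curve, higher score = more positive.

    Computed by the midrank identity, which equals the normalized count of
    (positive, negative) pairs with ties counting 1/2.
    """
    pos, neg = _split(scores, labels)
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent distinct observed scores
    (rule: score >= cutoff => positive). Ties in J are broken toward maximal
    specificity, then toward the larger threshold.
    """
    pos, neg = _split(scores, labels)
    distinct = np.unique(np.concatenate([pos, neg]))
    if distinct.size < 2:
        raise ValueError("need at least two distinct scores to place a cutoff")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in candidates:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > best[0]:
            best = (key, c)
    return float(best[1])


def operating_point(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> OperatingPoint:
    """Sensitivity/specificity/PPV/NPV (percent) at a cutoff; ratios with a
    zero denominator are returned as None."""
    pos, neg = _split(scores, labels)
    tp = int(np.sum(pos >= cutoff))
    fn = pos.size - tp
    fp = int(np.sum(neg >= cutoff))
    tn = neg.size - fp
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    ppv = 100.0 * tp / (tp + fp) if tp + fp else None
    npv = 100.0 * tn / (tn + fn) if tn + fn else None
    return OperatingPoint(sens, spec, ppv, npv)


def roc_analysis(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Full ROC report: AUC, Youden cutoff, and its operating point."""
    auc = roc_auc(scores, labels)
    cut = youden_cutoff(scores, labels)
    op = operating_point(scores, labels, cut)
    return RocResult(
        auc=auc,
        cutoff=cut,
        sensitivity=op.sensitivity,
        specificity=op.specificity,
        ppv=op.ppv,
        npv=op.npv,
        youden_j=op.sensitivity / 100.0 + op.specificity / 100.0 - 1.0,
    )
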