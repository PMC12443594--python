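"""Group-comparison statistics with exact small-sample implementations.

Exact distributions are used up to n = 12 per group (Mann-Whitney) or 12
pairs (Wilcoxon); above that a normal approximation with tie correction and
continuity correction is applied.  Fisher's exact test and the hypergeometric
upper tail are always exact (direct enumeration / summation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

EXACT_LIMIT = 12


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2, two-tailed)
# ---------------------------------------------------------------------------


def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Enumerates all tables with the observed margins and sums the probability
    of every table at most as probable as the observed one.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(
        1.0,
        sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12)),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _rank(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value (no ties), by DP."""
    # f[u] after adding each of the n1 "A" observations among n1+n2 ranks
    f = np.zeros(n1 * n2 + 1, dtype=float)
    f[0] = 1.0
    # recurrence over generating function prod_{i=1..n1} (1 - x^(n2+i)) / (1 - x^i)
    for i in range(1, n1 + 1):
        # multiply by 1/(1-x^i): prefix sums with stride i
        for u in range(i, n1 * n2 + 1):
            f[u] += f[u - i]
        # multiply by (1 - x^(n2+i))
        for u in range(n1 * n2, n2 + i - 1, -1):
            f[u] -= f[u - (n2 + i)]
    return f


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U for group A, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = _rank(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    has_ties = len(np.unique(combined)) < len(combined)

    if not has_ties and max(n1, n2) <= EXACT_LIMIT:
        counts = _exact_u_cdf(n1, n2)
        total = counts.sum()
        u_int = int(round(u))
        u_min = min(u_int, n1 * n2 - u_int)
        p = min(1.0, 2.0 * counts[: u_min + 1].sum() / total)
        return u, p

    n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = 0.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    return u, min(1.0, 2.0 * norm.sf(max(z, 0.0)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]] | Sequence[float]) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired data.

    Accepts (x, y) pairs or precomputed differences.  Zero differences are
    dropped; all-zero input returns p = 1 with a warning.  Exact sign-flip
    enumeration for <= 12 non-zero pairs (valid under ties), normal
    approximation with tie correction above.
    """
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    if len(diffs) == 0:
        raise ValueError("no pairs supplied")
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    n = len(diffs)
    ranks = _rank(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()

    if n <= EXACT_LIMIT:
        m = ranks.sum()
        w_lo = min(w_plus, m - w_plus)
        w_hi = m - w_lo
        count = 0
        eps = 1e-9
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if w <= w_lo + eps or w >= w_hi - eps:
                count += 1
        return w_plus, min(1.0, count / 2**n)

    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - ((tie_counts**3 - tie_counts).sum()) / 48
    if sigma2 <= 0:
        return w_plus, 1.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(sigma2)
    return w_plus, min(1.0, 2.0 * norm.sf(max(z, 0.0)))


# ---------------------------------------------------------------------------
# Hypergeometric upper tail
# ---------------------------------------------------------------------------


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    hi = min(K, n)
    if k > hi:
        return 0.0
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1)) / denom


# ---------------------------------------------------------------------------
# Figure-level helpers
# ---------------------------------------------------------------------------


@dataclass
class GroupDesign:
    """Two-group sample design, optionally with a pairing key."""

    labels: Mapping[str, str]  # sample_id -> group label
    pairing: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = set(self.labels.values())
        if len(groups) != 2:
            raise ValueError(f"design needs exactly two groups, got {sorted(groups)}")
        self.groups = tuple(sorted(groups))

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]


def build_threshold_contingency(
    quant_tables: Mapping[str, pd.DataFrame],
    design: GroupDesign,
    threshold_model,
) -> list[list[int]]:
    """2x2 table of distinct junctions above/below threshold per group.

    Rows: above, below.  Columns: design groups in sorted label order.
    """
    from .lam_junction_caller import apply_threshold

    counts = {g: [0, 0] for g in design.groups}
    for sample_id, table in quant_tables.items():
        if sample_id not in design.labels:
            raise KeyError(f"sample {sample_id!r} missing from design")
        group = design.labels[sample_id]
        thresholded = apply_threshold(table, threshold_model)
        above = int(thresholded["above_threshold"].sum())
        counts[group][0] += above
        counts[group][1] += len(thresholded) - above
    g1, g2 = design.groups
    return [[counts[g1][0], counts[g2][0]], [counts[g1][1], counts[g2][1]]]


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p values (optional; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj.tolist()
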