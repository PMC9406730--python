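"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (flood fill, exhaustive scans, full
enumeration, textbook sums-of-squares arithmetic) and shares no code with
the package.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


# ---------------------------------------------------------------------------
# connected components: iterative flood fill

N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
N8 = N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[frozenset]:
    """All connected components of a 2D boolean mask as pixel-coordinate sets."""
    offsets = N8 if connectivity == 8 else N4
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(ny):
        for sx in range(nx):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = set()
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            comps.append(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# Otsu: exhaustive between-class variance scan


def between_class_variance(values: np.ndarray, t: float) -> float:
    """Weighted between-class variance for the split v <= t vs v > t."""
    values = np.asarray(values, dtype=float).ravel()
    lo = values[values <= t]
    hi = values[values > t]
    if len(lo) == 0 or len(hi) == 0:
        return 0.0
    w0, w1 = len(lo) / len(values), len(hi) / len(values)
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def otsu_bruteforce_max(values: np.ndarray) -> float:
    """Maximum between-class variance over every candidate integer level."""
    values = np.asarray(values).ravel()
    candidates = np.arange(int(values.min()), int(values.max()))
    return max(between_class_variance(values, t) for t in candidates)


# ---------------------------------------------------------------------------
# ANOVA sums-of-squares decompositions


def oneway_f_oracle(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """(F, df1, df2) from the between/within SS decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    return (ss_between / df1) / (ss_within / df2), df1, df2


def twoway_balanced_f_oracle(cells: dict[tuple[str, str], np.ndarray]):
    """Classical balanced two-way decomposition.

    ``cells`` maps (a_level, b_level) -> replicate values, all equal n.
    Returns {"A": (F, df1, df2), "B": ..., "AB": ...}.
    """
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    assert all(len(v) == n for v in cells.values())
    allv = np.concatenate(list(cells.values()))
    grand = allv.mean()
    a_means = {a: np.concatenate([cells[(a, b)] for b in b_levels]).mean() for a in a_levels}
    b_means = {b: np.concatenate([cells[(a, b)] for a in a_levels]).mean() for b in b_levels}
    cell_means = {k: v.mean() for k, v in cells.items()}

    ss_a = n * len(b_levels) * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels for b in b_levels
    )
    ss_e = sum(((cells[k] - cell_means[k]) ** 2).sum() for k in cells)
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(allv) - len(a_levels) * len(b_levels)
    return {
        "A": ((ss_a / df_a) / (ss_e / df_e), df_a, df_e),
        "B": ((ss_b / df_b) / (ss_e / df_e), df_b, df_e),
        "AB": ((ss_ab / df_ab) / (ss_e / df_e), df_ab, df_e),
    }


# ---------------------------------------------------------------------------
# rank tests


def rankdata_simple(values: np.ndarray) -> np.ndarray:
    """Midranks computed from first principles."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kruskal_h_oracle(groups: list[np.ndarray]) -> float:
    """Tie-corrected H from the rank-sum formula."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = rankdata_simple(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


def mannwhitney_exact_p_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U, two-sided exact p) by enumerating all C(n1+n2, n1) labelings.

    Tie-free inputs only.  U is the smaller of the two sample statistics;
    p is twice the smaller tail, capped at 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = rankdata_simple(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_obs = min(u1, n1 * n2 - u1)

    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    total = comb(n1 + n2, n1)
    p_le = np.sum(us <= u1) / total
    p_ge = np.sum(us >= u1) / total
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))
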