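"""Group-comparison statistics for per-hemisphere quantification tables.

The battery mirrors a standard reporter-assay analysis: two-way fixed-effects
ANOVA (treatment x developmental stage, Type II sums of squares for
unbalanced designs), one-way ANOVA with Bonferroni all-pairs post hoc,
Kruskal-Wallis ("one-way ANOVA on ranks", tie-corrected H on a chi-square
reference with k-1 df) with Dunn + Bonferroni post hoc, and the two-sided
Mann-Whitney rank-sum test (exact by enumeration for small tie-free samples,
otherwise normal approximation with tie and continuity corrections).
Group summaries are reported as mean +/- SEM.  The statistical unit is one
hemisphere stack (one table row); rows with an undefined response (e.g. a
0/0 overlap proportion) are dropped from that response's test, with the
drop count recorded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupSummary",
    "StatReport",
    "two_way_anova",
    "one_way_anova",
    "kruskal_wallis",
    "mann_whitney",
    "summarize_groups",
]

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

POSTHOC_COLUMNS = ("group_a", "group_b", "statistic", "p_raw", "p_adj")


@dataclass
class GroupSummary:
    """n, mean and SEM (sample SD / sqrt(n); undefined for n = 1)."""

    group: str
    n: int
    mean: float
    sem: float | None


@dataclass
class StatReport:
    """One statistical comparison, ready for tabular serialization."""

    test: str
    response: str
    statistics: dict[str, float]           # e.g. {"F_treatment": ..} or {"H": ..}, {"U": ..}
    df: dict[str, tuple]                   # per-term degrees of freedom
    p_values: dict[str, float]
    alpha: float = ALPHA_DEFAULT
    posthoc: pd.DataFrame | None = None    # columns POSTHOC_COLUMNS
    group_summaries: list[GroupSummary] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for term, p in self.p_values.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p value for {term} outside [0, 1]: {p}")
        if self.posthoc is not None:
            bad = self.posthoc[(self.posthoc["p_adj"] < 0) | (self.posthoc["p_adj"] > 1)]
            if len(bad):
                raise ValueError("adjusted p outside [0, 1]")


def _drop_missing(table: pd.DataFrame, response: str) -> tuple[pd.DataFrame, int]:
    n0 = len(table)
    out = table.dropna(subset=[response])
    dropped = n0 - len(out)
    if dropped:
        logger.info("response %s: dropped %d row(s) with undefined values", response, dropped)
    return out, dropped


def summarize_groups(
    table: pd.DataFrame, response: str, group_cols: str | Sequence[str]
) -> list[GroupSummary]:
    """Per-group n / mean / SEM of ``response``; missing responses dropped."""
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    table, _ = _drop_missing(table, response)
    out = []
    for key, sub in table.groupby(list(group_cols), sort=True):
        label = key if isinstance(key, str) else ":".join(map(str, np.atleast_1d(key)))
        vals = sub[response].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else None
        out.append(GroupSummary(group=label, n=n, mean=float(vals.mean()), sem=sem))
    return out


# ---------------------------------------------------------------------------
# ANOVA


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    alpha: float = ALPHA_DEFAULT,
    ss_type: int = 2,
) -> StatReport:
    """Fixed-effects two-way ANOVA with interaction.

    Type II sums of squares by default, which reduces to the classical
    balanced decomposition when cell sizes are equal.
    """
    table, dropped = _drop_missing(table, response)
    for fac in (factor_a, factor_b):
        if table[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    cells = table.groupby([factor_a, factor_b]).size()
    full = itertools.product(table[factor_a].unique(), table[factor_b].unique())
    for cell in full:
        if cell not in cells.index:
            raise ValueError(f"empty design cell {cell} for {factor_a} x {factor_b}")

    data = table[[response, factor_a, factor_b]].copy()
    data.columns = ["y", "A", "B"]
    model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    df_resid = float(aov.loc["Residual", "df"])

    terms = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": "interaction"}
    statistics, dfs, p_values = {}, {}, {}
    for key, name in terms.items():
        statistics[f"F_{name}"] = float(aov.loc[key, "F"])
        dfs[name] = (float(aov.loc[key, "df"]), df_resid)
        p_values[name] = float(aov.loc[key, "PR(>F)"])

    return StatReport(
        test="anova2",
        response=response,
        statistics=statistics,
        df=dfs,
        p_values=p_values,
        alpha=alpha,
        group_summaries=summarize_groups(table, response, [factor_a, factor_b]),
        n_dropped=dropped,
    )


def _bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def one_way_anova(
    table: pd.DataFrame,
    response: str,
    group: str,
    alpha: float = ALPHA_DEFAULT,
    posthoc: str = "bonferroni",
) -> StatReport:
    """One-way ANOVA; Bonferroni all-pairs t post hoc when p <= alpha.

    Pairwise raw p values come from pooled-variance two-sample t tests and
    are adjusted as min(1, m * p_raw) over the m pairs, so a pair of
    indistinguishable groups is reported with an adjusted p capped at 1.0.
    """
    table, dropped = _drop_missing(table, response)
    levels = sorted(table[group].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {group!r} needs >= 2 levels")
    samples = {g: table.loc[table[group] == g, response].to_numpy(dtype=float) for g in levels}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n = {len(v)} < 2")

    f_stat, p = sps.f_oneway(*samples.values())
    k = len(levels)
    n_total = sum(len(v) for v in samples.values())
    df = {"group": (float(k - 1), float(n_total - k))}

    posthoc_df = None
    if posthoc == "bonferroni" and p <= alpha:
        pairs = list(itertools.combinations(levels, 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            t, p_raw = sps.ttest_ind(samples[a], samples[b], equal_var=True)
            if np.isnan(p_raw):  # both groups constant and equal
                t, p_raw = 0.0, 1.0
            rows.append((a, b, float(t), float(p_raw), _bonferroni(float(p_raw), m)))
        posthoc_df = pd.DataFrame(rows, columns=list(POSTHOC_COLUMNS))

    return StatReport(
        test="anova1",
        response=response,
        statistics={"F": float(f_stat)},
        df=df,
        p_values={"group": float(p)},
        alpha=alpha,
        posthoc=posthoc_df,
        group_summaries=summarize_groups(table, response, group),
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(
    table: pd.DataFrame,
    response: str,
    group: str,
    alpha: float = ALPHA_DEFAULT,
    posthoc: str = "bonferroni",
) -> StatReport:
    """Kruskal-Wallis H (tie-corrected) with Dunn + Bonferroni post hoc."""
    table, dropped = _drop_missing(table, response)
    levels = sorted(table[group].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {group!r} needs >= 2 levels")
    samples = {g: table.loc[table[group] == g, response].to_numpy(dtype=float) for g in levels}
    n_total = sum(len(v) for v in samples.values())
    if n_total < 3:
        raise ValueError("Kruskal-Wallis requires total N >= 3")

    all_vals = np.concatenate(list(samples.values()))
    if np.all(all_vals == all_vals[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples.values())

    posthoc_df = None
    if posthoc == "bonferroni" and p <= alpha:
        posthoc_df = _dunn_posthoc(samples)

    return StatReport(
        test="kruskal_wallis",
        response=response,
        statistics={"H": float(h)},
        df={"group": (float(len(levels) - 1),)},
        p_values={"group": float(p)},
        alpha=alpha,
        posthoc=posthoc_df,
        group_summaries=summarize_groups(table, response, group),
        n_dropped=dropped,
    )


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z tests on pooled mean ranks, Bonferroni-adjusted."""
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        n = len(samples[g])
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p_raw), _bonferroni(float(p_raw), m)))
    return pd.DataFrame(rows, columns=list(POSTHOC_COLUMNS))


EXACT_MW_MAX_N = 12


def _mw_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    us = [
        sum(combo) - n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(1, n1 + n2 + 1), n1)
    ]
    us = np.asarray(us, dtype=float)
    total = len(us)
    p_le = np.sum(us <= u_obs) / total
    p_ge = np.sum(us >= u_obs) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatReport:
    """Two-sided Mann-Whitney rank-sum test.

    Exact by enumeration of all C(n1+n2, n1) rank assignments when
    n1 + n2 <= 12 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.  The reported U is the
    smaller of the two sample statistics, U = n1*n2/2 meaning perfect
    overlap.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples need n >= 1")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if np.all(pooled == pooled[0]):
        p = 1.0
    elif not has_ties and n1 + n2 <= EXACT_MW_MAX_N:
        p = _mw_exact_p(x, y)
    else:
        _, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(1.0, p))

    summaries = [
        GroupSummary("x", n1, float(x.mean()),
                     float(np.std(x, ddof=1) / np.sqrt(n1)) if n1 > 1 else None),
        GroupSummary("y", n2, float(y.mean()),
                     float(np.std(y, ddof=1) / np.sqrt(n2)) if n2 > 1 else None),
    ]
    return StatReport(
        test="mann_whitney",
        response="",
        statistics={"U": u, "U_x": u1, "U_y": u2},
        df={},
        p_values={"U": p},
        group_summaries=summaries,
    )
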