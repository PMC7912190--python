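"""Between-group statistical comparison battery.

Regional comparisons of housing and microclimate variables follow the
test-family decision used throughout smallholder-farm survey work:
Shapiro–Wilk decides normal vs non-normal; normal variables get one-way
ANOVA with Tukey–Kramer post hocs, non-normal ones get Kruskal–Wallis with
Dunn post hocs (Holm-adjusted by default), and categorical variables get an
exact R×C Fisher test with Bonferroni-corrected pairwise 2×2 Fisher tests.
Pairwise outcomes are condensed to a compact letter display (groups sharing
a letter do not differ at α = 0.05).  A two-way ANOVA (Type-II sums of
squares) compares microclimate between housing clusters while adjusting for
altitude and latitude.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "normality_gate",
    "anova_tukey",
    "kruskal_dunn",
    "fisher_battery",
    "fisher_exact_rxc",
    "cluster_twoway_anova",
    "compact_letter_display",
]


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    letters: dict = field(default_factory=dict)
    adjustment: str = ""
    notes: str = ""


def normality_gate(values, groups, alpha: float = 0.05):
    """Decide the test family from Shapiro–Wilk on pooled group residuals.

    Residuals are values minus their group mean; constant data is
    non-normal by convention.  Returns ``("normal"|"non-normal", p)``.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.size < 3:
        raise ValueError("need at least 3 observations for the normality gate")
    resid = np.concatenate([x[g == lev] - x[g == lev].mean()
                            for lev in pd.unique(g)])
    if np.ptp(resid) == 0:
        return "non-normal", 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.shapiro(resid)
    return ("normal" if p >= alpha else "non-normal"), float(p)


def compact_letter_display(group_names, means, sig_pairs) -> dict:
    """Compact letter display from pairwise significance.

    ``sig_pairs`` is a set of frozensets of group names that differ
    significantly.  Groups are ordered by descending mean; maximal runs of
    mutually non-significant groups share a letter.  Invariant under label
    permutation of the input order.
    """
    order = [g for _, g in sorted(zip(means, group_names),
                                  key=lambda t: (-t[0], str(t[1])))]
    runs = []
    for i in range(len(order)):
        j = i
        while (j + 1 < len(order)
               and all(frozenset((order[a], order[b])) not in sig_pairs
                       for a in range(i, j + 2) for b in range(a + 1, j + 2))):
            j += 1
        runs.append(tuple(order[i:j + 1]))
    # drop runs contained in another run
    runs = [r for r in runs
            if not any(set(r) < set(o) for o in runs if o != r)]
    seen, uniq = set(), []
    for r in runs:
        if r not in seen:
            seen.add(r)
            uniq.append(r)
    letters = {g: "" for g in group_names}
    for letter, run in zip("abcdefghijklmnopqrstuvwxyz", uniq):
        for g in run:
            letters[g] += letter
    return letters


def _summary(x, g):
    rows = []
    for lev in pd.unique(g):
        sub = x[g == lev]
        rows.append({"group": lev, "n": sub.size, "mean": sub.mean(),
                     "median": float(np.median(sub)), "sd": sub.std(ddof=1)
                     if sub.size > 1 else 0.0})
    return pd.DataFrame(rows)


def anova_tukey(values, groups, alpha: float = 0.05,
                variable: str = "") -> ComparisonResult:
    """One-way ANOVA with Tukey–Kramer pairwise comparisons (unequal n ok)."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep_levels = [lev for lev in pd.unique(g) if (g == lev).sum() >= 2]
    dropped = set(pd.unique(g)) - set(keep_levels)
    if dropped:
        warnings.warn(f"excluding groups with <2 observations: {sorted(map(str, dropped))}")
        mask = np.isin(g, keep_levels)
        x, g = x[mask], g[mask]
    if len(keep_levels) < 2:
        raise ValueError("need at least two groups with >=2 observations")
    samples = [x[g == lev] for lev in keep_levels]
    F, p = stats.f_oneway(*samples)
    tuk = pairwise_tukeyhsd(x, g, alpha=alpha)
    pw = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    sig = {frozenset((r["group1"], r["group2"]))
           for _, r in pw.iterrows() if bool(r["reject"])}
    means = [s.mean() for s in samples]
    letters = compact_letter_display(keep_levels, means, sig)
    return ComparisonResult(variable=variable, test="one-way ANOVA + Tukey-Kramer",
                            statistic=float(F), p_value=float(p),
                            group_summary=_summary(x, g), pairwise=pw,
                            letters=letters, adjustment="Tukey-Kramer")


def _dunn_pairwise(x, g, levels, adjust="holm"):
    """Dunn's rank-based z tests with tie correction."""
    N = x.size
    ranks = stats.rankdata(x)
    _, counts = np.unique(x, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ra, rb = ranks[g == a], ranks[g == b]
        se = math.sqrt(max(var_base, 0.0) * (1 / ra.size + 1 / rb.size))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        rows.append({"group1": a, "group2": b, "z": z,
                     "p_raw": 2 * stats.norm.sf(abs(z))})
    pw = pd.DataFrame(rows)
    if adjust:
        pw["p_adj"] = multipletests(pw["p_raw"], method=adjust)[1]
    else:
        pw["p_adj"] = pw["p_raw"]
    return pw


def kruskal_dunn(values, groups, alpha: float = 0.05, adjust: str = "holm",
                 variable: str = "") -> ComparisonResult:
    """Kruskal–Wallis (tie-corrected) with Dunn post hoc tests."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [x[g == lev] for lev in levels]
    if np.ptp(x) == 0:
        H, p = 0.0, 1.0
        pw = _dunn_pairwise(x, g, levels, adjust) if x.size else pd.DataFrame()
    else:
        H, p = stats.kruskal(*samples)
        pw = _dunn_pairwise(x, g, levels, adjust)
    sig = {frozenset((r["group1"], r["group2"]))
           for _, r in pw.iterrows() if r["p_adj"] < alpha}
    medians = [float(np.median(s)) for s in samples]
    letters = compact_letter_display(levels, medians, sig)
    return ComparisonResult(variable=variable, test="Kruskal-Wallis + Dunn",
                            statistic=float(H), p_value=float(p),
                            group_summary=_summary(x, g), pairwise=pw,
                            letters=letters, adjustment=adjust)


def _rxc_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    R, C = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols):
        if row_idx == R - 1:
            yield (tuple(remaining_cols),)
            return
        r = row_sums[row_idx]

        def row_fill(j, left, acc):
            if j == C - 1:
                if left <= remaining_cols[j]:
                    yield acc + (left,)
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                yield from row_fill(j + 1, left - v, acc + (v,))

        for row in row_fill(0, r, ()):
            rest = [remaining_cols[j] - row[j] for j in range(C)]
            for tail in rec(row_idx + 1, rest):
                yield (row,) + tail

    yield from rec(0, list(col_sums))


def _log_table_prob(table, row_sums, col_sums, n, lgamma=math.lgamma):
    lp = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    lp -= lgamma(n + 1)
    for row in table:
        for v in row:
            lp -= lgamma(v + 1)
    return lp


def fisher_exact_rxc(counts, max_tables: int = 200_000,
                     mc_draws: int = 100_000, seed: int = 0
                     ) -> tuple[float, str]:
    """Two-sided exact p for an R×C contingency table with fixed margins.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (conditional multivariate hypergeometric).  Beyond ``max_tables``
    candidate tables the p-value is estimated by Monte Carlo with a fixed
    seed instead; the method used is returned alongside the p-value.
    """
    M = np.asarray(counts, dtype=int)
    if np.any(M < 0):
        raise ValueError("counts must be non-negative integers")
    row_sums, col_sums = M.sum(axis=1), M.sum(axis=0)
    keep_r, keep_c = row_sums > 0, col_sums > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping empty rows/columns from the contingency table")
        M = M[keep_r][:, keep_c]
        row_sums, col_sums = M.sum(axis=1), M.sum(axis=0)
    if M.shape[0] < 2 or M.shape[1] < 2:
        return 1.0, "degenerate"
    n = int(M.sum())
    lp_obs = _log_table_prob(tuple(map(tuple, M)), row_sums, col_sums, n)
    # cheap upper bound on the number of candidate tables
    bound = 1.0
    for r in row_sums[:-1]:
        bound *= math.comb(int(r) + len(col_sums) - 1, len(col_sums) - 1)
        if bound > max_tables:
            break
    if bound <= max_tables:
        total = 0.0
        for tab in _rxc_tables([int(r) for r in row_sums],
                               [int(c) for c in col_sums]):
            lp = _log_table_prob(tab, row_sums, col_sums, n)
            if lp <= lp_obs + 1e-9:
                total += math.exp(lp)
        return min(total, 1.0), "enumeration"
    # Monte Carlo over tables with fixed margins via random permutations
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(len(row_sums)), row_sums)
    col_of = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(mc_draws):
        perm = rng.permutation(col_of)
        tab = np.zeros_like(M)
        np.add.at(tab, (row_of, perm), 1)
        lp = _log_table_prob(tuple(map(tuple, tab)), row_sums, col_sums, n)
        if lp <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (mc_draws + 1), "monte-carlo"


def fisher_battery(counts: pd.DataFrame, alpha: float = 0.05,
                   variable: str = "", seed: int = 0) -> ComparisonResult:
    """Exact R×C Fisher test with Bonferroni-corrected pairwise 2×2 tests.

    ``counts`` is a groups × categories table of non-negative integers.
    Pairwise tests compare each pair of groups on the (first-vs-rest)
    category split when C > 2, or the 2×2 subtable when C = 2, with p
    multiplied by the number of pairs (capped at 1).
    """
    M = counts.to_numpy(dtype=int)
    p, method = fisher_exact_rxc(M, seed=seed)
    groups = list(counts.index)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        sub = M[[i, j]]
        if sub.shape[1] > 2:
            sub = np.column_stack([sub[:, 0], sub[:, 1:].sum(axis=1)])
        if sub.sum(axis=0).min() == 0 or sub.sum(axis=1).min() == 0:
            praw = 1.0
        else:
            _, praw = stats.fisher_exact(sub)
        rows.append({"group1": groups[i], "group2": groups[j], "p_raw": praw,
                     "p_adj": min(1.0, praw * len(pairs))})
    pw = pd.DataFrame(rows)
    sig = {frozenset((r["group1"], r["group2"]))
           for _, r in pw.iterrows() if r["p_adj"] < alpha}
    # order groups by first-category share for the letter display
    shares = M[:, 0] / np.maximum(M.sum(axis=1), 1)
    letters = compact_letter_display(groups, shares, sig)
    summary = counts.copy()
    summary["pct_first_category"] = 100 * shares
    return ComparisonResult(variable=variable,
                            test=f"Fisher exact ({method}) + pairwise Fisher",
                            statistic=float("nan"), p_value=float(p),
                            group_summary=summary.reset_index(),
                            pairwise=pw, letters=letters,
                            adjustment="Bonferroni", notes=method)


def cluster_twoway_anova(data: pd.DataFrame, response: str,
                         cluster_col: str = "cluster",
                         altitude_col: str = "altitude",
                         latitude_col: str = "latitude_class",
                         min_cluster_size: int = 4) -> ComparisonResult:
    """Cluster effect on a microclimate response, adjusting for altitude and
    latitude (Type-II sums of squares).

    Clusters with fewer than ``min_cluster_size`` members (default: more
    than three required) are excluded before fitting.
    """
    sizes = data[cluster_col].value_counts()
    eligible = sizes[sizes >= min_cluster_size].index
    if len(eligible) < 2:
        raise ValueError("fewer than two clusters with enough members")
    df = data[data[cluster_col].isin(eligible)].copy()
    df["_cluster"] = df[cluster_col].astype(str)
    terms = [f"C(_cluster)", altitude_col]
    if df[latitude_col].nunique() > 1:
        terms.append(f"C({latitude_col})")
    model = smf.ols(f"{response} ~ " + " + ".join(terms), data=df).fit()
    tab = anova_lm(model, typ=2)
    F = float(tab.loc["C(_cluster)", "F"])
    p = float(tab.loc["C(_cluster)", "PR(>F)"])
    summ = (df.groupby("_cluster")[response]
            .agg(["count", "mean", "std"]).reset_index()
            .rename(columns={"_cluster": "cluster"}))
    return ComparisonResult(variable=response,
                            test="two-way ANOVA (cluster + altitude + latitude)",
                            statistic=F, p_value=p, group_summary=summ,
                            pairwise=tab.reset_index(), adjustment="Type-II SS")
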