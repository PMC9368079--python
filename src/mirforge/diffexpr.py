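"""Normalisation and differential-expression calling for miRNA counts.

Counts are normalised to counts-per-million (CPM).  The test battery is
dispatched by design: Student's t-test on log2(CPM+1) for replicated
two-group comparisons, one-way ANOVA for more than two replicated
groups, and pooled 2x2 count tests (Fisher's exact test when any
expected cell is below 5, otherwise the chi-squared test) or an n-by-n
chi-squared test when libraries are unreplicated.  A miRNA is called
differentially expressed when |log2 fold change| >= 1 and raw p < alpha
(alpha in [0.01, 0.05]); Benjamini-Hochberg q-values are reported
alongside but do not gate the call.

The two-sided Fisher p-value is computed in-package by exact integer
hypergeometric enumeration: the probabilities of all tables sharing the
observed margins are compared as exact integers, so ties are handled
without floating-point tolerances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDO_CPM = 1.0


class NormalizationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """miRNA x library counts with group assignments."""

    counts: pd.DataFrame                 # rows miRNAs, columns libraries
    groups: dict[str, str]               # library -> group label

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"libraries without group assignment: {sorted(missing)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def libraries_of(self, group: str) -> list[str]:
        return [lib for lib in self.counts.columns if self.groups[lib] == group]


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size x 1e6, per column."""
    sizes = counts.sum(axis=0)
    zero = sizes[sizes == 0]
    if len(zero):
        raise NormalizationError(
            f"zero library size for: {', '.join(map(str, zero.index))}")
    return counts / sizes * 1e6


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.  Numerators
    are compared as exact integers (shared denominator), so equally
    probable tables are included without any tolerance.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
    obs = nums[a - kmin]
    total = sum(nums)
    tail = sum(x for x in nums if x <= obs)
    return min(1.0, tail / total)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared test of homogeneity, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.min() < 0:
        raise ValueError("table entries must be non-negative")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _student_t(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pooled-variance t p-value.

    Identical replicate vectors are a perfect null (p = 1).  When both
    groups have zero variance but different means the t statistic is
    undefined; returning None lets the caller fall back to a pooled
    count test instead of over-calling miRNAs seen a handful of times.
    """
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else None
    res = stats.ttest_ind(x, y, equal_var=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def test_differential(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    pseudo: float = PSEUDO_CPM,
) -> pd.DataFrame:
    """Per-miRNA two-group differential test with policy dispatch.

    log2fc is log2((mean CPM_b + pseudo) / (mean CPM_a + pseudo)),
    i.e. positive when expression is higher in ``group_b``.
    """
    libs_a = matrix.libraries_of(group_a)
    libs_b = matrix.libraries_of(group_b)
    if not libs_a or not libs_b:
        raise ValueError("each group needs at least one library")
    cpm = normalize_cpm(matrix.counts)
    mean_a = cpm[libs_a].mean(axis=1)
    mean_b = cpm[libs_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    replicated = len(libs_a) >= 2 and len(libs_b) >= 2

    rows = []
    counts = matrix.counts
    size_a = int(counts[libs_a].sum().sum())
    size_b = int(counts[libs_b].sum().sum())
    log_a = np.log2(cpm[libs_a] + pseudo)
    log_b = np.log2(cpm[libs_b] + pseudo)

    def _pooled_count_test(xa: int, xb: int) -> tuple[float, str]:
        table = [[xa, size_a - xa], [xb, size_b - xb]]
        if _min_expected(table) < 5:
            return fisher_exact_two_sided(table), "fisher"
        stat_, p_ = chi2_2x2(table)
        return p_, "chi2_2x2"

    for i, mirna in enumerate(counts.index):
        ca = counts.loc[mirna, libs_a]
        cb = counts.loc[mirna, libs_b]
        degenerate = (ca.sum() == 0) and (cb.sum() == 0)
        if degenerate:
            p, test = 1.0, "degenerate"
        elif replicated:
            p = _student_t(log_a.loc[mirna].to_numpy(), log_b.loc[mirna].to_numpy())
            test = "t"
            if p is None:
                p, test = _pooled_count_test(int(ca.sum()), int(cb.sum()))
        else:
            p, test = _pooled_count_test(int(ca.sum()), int(cb.sum()))
        rows.append({
            "mirna": mirna, "group_a": group_a, "group_b": group_b,
            "log2fc": 0.0 if degenerate else float(log2fc.iloc[i]),
            "p": float(p), "test": test, "degenerate": degenerate,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def test_anova(matrix: CountMatrix, groups: list[str],
               pseudo: float = PSEUDO_CPM) -> pd.DataFrame:
    """One-way ANOVA (replicated) or n-by-n chi-squared (unreplicated)
    across more than two groups."""
    if len(groups) < 3:
        raise ValueError("use test_differential for two groups")
    libsets = [matrix.libraries_of(g) for g in groups]
    if any(not libs for libs in libsets):
        raise ValueError("every group needs at least one library")
    replicated = all(len(libs) >= 2 for libs in libsets)
    cpm = normalize_cpm(matrix.counts)
    logcpm = np.log2(cpm + pseudo)
    rows = []
    if not replicated:
        sizes = [int(matrix.counts[libs].sum().sum()) for libs in libsets]
    for mirna in matrix.counts.index:
        if matrix.counts.loc[mirna].sum() == 0:
            rows.append({"mirna": mirna, "p": 1.0, "test": "degenerate"})
            continue
        if replicated:
            samples = [logcpm.loc[mirna, libs].to_numpy() for libs in libsets]
            if all(np.var(s) == 0 for s in samples):
                means = [np.mean(s) for s in samples]
                p = 1.0 if len(set(means)) == 1 else 0.0
            else:
                p = float(stats.f_oneway(*samples).pvalue)
            test = "anova"
        else:
            xs = [int(matrix.counts.loc[mirna, libs].sum()) for libs in libsets]
            table = [[x, s - x] for x, s in zip(xs, sizes)]
            _, p, _, _ = stats.chi2_contingency(np.array(table, float).T,
                                                correction=False)
            test = "nxn_chi2"
        rows.append({"mirna": mirna, "p": float(p), "test": test})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _min_expected(table) -> float:
    t = np.asarray(table, dtype=float)
    rs, cs, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    return float((np.outer(rs, cs) / n).min())


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def call_demirnas(
    results: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the DE gates: |log2fc| >= fc_threshold and raw p < alpha.

    Returns the result table (sorted by p then name, with ``direction``
    and ``de`` columns) and the up/down tallies.
    """
    if not 0.01 <= alpha <= 0.05:
        warnings.warn(f"alpha {alpha} outside the conventional [0.01, 0.05] band")
    out = results.copy()
    out["de"] = (out["log2fc"].abs() >= fc_threshold) & (out["p"] < alpha)
    out["direction"] = np.where(
        ~out["de"], "ns", np.where(out["log2fc"] > 0, "up", "down"))
    out = out.sort_values(["p", "mirna"], kind="mergesort").reset_index(drop=True)
    tallies = {
        "up": int((out["direction"] == "up").sum()),
        "down": int((out["direction"] == "down").sum()),
        "total_de": int(out["de"].sum()),
    }
    return out, tallies


def zscore_matrix(cpm: pd.DataFrame, pseudo: float = PSEUDO_CPM) -> pd.DataFrame:
    """Row z-scores of log2(CPM+pseudo), for external heat-map tools."""
    lg = np.log2(cpm + pseudo)
    mu = lg.mean(axis=1)
    sd = lg.std(axis=1).replace(0, 1.0)
    return lg.sub(mu, axis=0).div(sd, axis=0)
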