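"""Mutation-frequency estimation from plating data and exact rank testing.

A fluctuation-style measurement plates two aliquots of each culture: one on
selective medium (counting resistant colonies) and one on nonselective
medium (counting viable cells).  Each aliquot carries a fold-dilution factor
``d >= 1``, so ``colonies x d`` estimates the corresponding cell number in
the undiluted suspension and the mutant frequency of a culture is

    f = (n_selective * d_selective) / (n_nonselective * d_nonselective)

Groups of cultures (one strain/guide combination, replicates pooled) are
summarized by their *median* frequency; between-group effect sizes are
ratios of medians; significance is assessed with a two-tailed Mann-Whitney
U test whose p-value is computed exactly for small samples.

The exact test enumerates the null distribution of U by dynamic programming
when the pooled sample is tie-free, and by exhaustive enumeration of the
C(n+m, n) group assignments (with mid-rank U) when ties are present and the
enumeration is small enough; otherwise it falls back to the tie-corrected
normal approximation.  The method actually used is recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedFrequencyError(ValueError):
    """Raised when a culture has zero nonselective colonies."""


@dataclass(frozen=True)
class PlatingMeasurement:
    """Colony counts and fold-dilution factors for one culture."""

    culture_id: str
    group: str
    n_selective: int
    d_selective: float
    n_nonselective: int
    d_nonselective: float

    def __post_init__(self) -> None:
        if self.n_selective < 0 or self.n_nonselective < 0:
            raise ValueError(f"culture {self.culture_id}: negative colony count")
        if self.d_selective < 1 or self.d_nonselective < 1:
            raise ValueError(f"culture {self.culture_id}: dilution factors must be >= 1")


def mutation_frequency(m: PlatingMeasurement) -> float:
    """Mutant frequency of one culture from its plating counts and dilutions."""
    if m.n_nonselective == 0:
        raise UndefinedFrequencyError(
            f"culture {m.culture_id}: zero nonselective colonies, frequency undefined"
        )
    return (m.n_selective * m.d_selective) / (m.n_nonselective * m.d_nonselective)


@dataclass
class FrequencyResult:
    """Per-culture frequencies and the group median."""

    group: str
    frequencies: list[float]

    @property
    def n(self) -> int:
        return len(self.frequencies)

    @property
    def median(self) -> float:
        return float(np.median(self.frequencies))


def group_median(measurements: Iterable[PlatingMeasurement]) -> dict[str, FrequencyResult]:
    """Pool cultures by group label and compute per-group medians."""
    groups: dict[str, list[float]] = {}
    for m in measurements:
        groups.setdefault(m.group, []).append(mutation_frequency(m))
    return {g: FrequencyResult(g, fs) for g, fs in groups.items()}


def fold_change(group: FrequencyResult, reference: FrequencyResult) -> float:
    """Ratio of group medians, ``group`` relative to ``reference``.

    A zero reference median yields ``inf`` (flagged by the caller's report)
    rather than raising.
    """
    if group.n == 0 or reference.n == 0:
        raise ValueError("both groups must be non-empty")
    if reference.median == 0:
        return math.inf
    return group.median / reference.median


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_MAX_N = 20          # DP enumeration bound for tie-free pooled samples
PERMUTATION_MAX = 200_000  # combination budget for tie-aware exact enumeration


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str  # exact_dp | exact_permutation | normal_approx

    def __iter__(self):
        return iter((self.U, self.p))


def _rank_sum_counts(n: int, m: int) -> np.ndarray:
    """Null counts of the x rank-sum over all C(n+m, n) tie-free labelings.

    counts[s] = number of ways to choose n ranks from 1..n+m summing to
    s + n(n+1)/2 (i.e. index is the U statistic of x).
    """
    max_u = n * m
    # dp[k][u] = number of k-subsets of the ranks seen so far with U = u
    dp = np.zeros((n + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for rank in range(1, n + m + 1):
        # choosing this rank as an x observation adds (rank - k) ... handled
        # via the standard Gaussian-binomial recurrence: process ranks in
        # order; picking the j-th smallest x among the first `rank` ranks
        # contributes rank - j to U.
        for k in range(min(n, rank), 0, -1):
            add = rank - k  # number of y's below this x so far
            if add > max_u:
                continue
            dp[k, add:] += dp[k - 1, : max_u + 1 - add]
    return dp[n]


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x with mid-ranks for ties."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = stats.rankdata(pooled)
    n = len(x)
    r_x = ranks[:n].sum()
    return float(r_x - n * (n + 1) / 2)


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U test with an exact small-sample p-value.

    ``alternative`` is one of ``two-sided``, ``greater`` (x tends larger),
    ``less``.  The two-sided p is ``min(1, 2 * smaller one-sided tail)``.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    has_ties = len(set(x + y)) < n + m

    if not has_ties and n + m <= EXACT_MAX_N:
        counts = _rank_sum_counts(n, m)
        total = counts.sum()
        u_int = int(round(u_obs))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
        method = "exact_dp"
    elif math.comb(n + m, n) <= PERMUTATION_MAX:
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        base = n * (n + 1) / 2
        us = np.array(
            [ranks[list(idx)].sum() - base for idx in combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_ge = float(np.mean(us >= u_obs - eps))
        p_le = float(np.mean(us <= u_obs + eps))
        method = "exact_permutation"
    else:
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        p_ge = float(res.pvalue)
        res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        p_le = float(res.pvalue)
        method = "normal_approx"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return MannWhitneyResult(U=u_obs, p=float(p), method=method)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties.

    Raises on constant input (rho undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Tabular I/O and group reports
# ---------------------------------------------------------------------------

PLATING_COLUMNS = [
    "culture_id", "group", "n_selective", "d_selective", "n_nonselective", "d_nonselective",
]


def read_plating(path: str | Path) -> list[PlatingMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        PlatingMeasurement(
            culture_id=str(row["culture_id"]),
            group=str(row["group"]),
            n_selective=int(row["n_selective"]),
            d_selective=float(row["d_selective"]),
            n_nonselective=int(row["n_nonselective"]),
            d_nonselective=float(row["d_nonselective"]),
        )
        for _, row in df.iterrows()
    ]


def write_plating(measurements: Iterable[PlatingMeasurement], path: str | Path) -> None:
    rows = [
        {
            "culture_id": m.culture_id, "group": m.group,
            "n_selective": m.n_selective, "d_selective": m.d_selective,
            "n_nonselective": m.n_nonselective, "d_nonselective": m.d_nonselective,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=PLATING_COLUMNS).to_csv(path, sep="\t", index=False)


def frequency_report(
    measurements: Sequence[PlatingMeasurement],
    reference_group: str | None = None,
) -> dict:
    """Per-group medians, fold-changes vs. a named control, pairwise exact MWU p-values.

    Frequencies are reported to 3 significant digits and p-values to 4
    decimal places.
    """
    groups = group_median(measurements)
    report: dict = {"groups": {}, "pairwise": []}
    for g, res in sorted(groups.items()):
        entry = {
            "n": res.n,
            "median": float(f"{res.median:.3g}"),
        }
        if reference_group is not None and g != reference_group:
            if reference_group not in groups:
                raise ValueError(f"reference group {reference_group!r} not present")
            fc = fold_change(res, groups[reference_group])
            entry["fold_vs_reference"] = "inf" if math.isinf(fc) else float(f"{fc:.3g}")
            entry["reference"] = reference_group
        report["groups"][g] = entry
    names = sorted(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            res = mann_whitney_exact(groups[a].frequencies, groups[b].frequencies)
            report["pairwise"].append(
                {"a": a, "b": b, "U": res.U, "p": round(res.p, 4), "method": res.method}
            )
    return report
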