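"""Summary statistics for the specificity audit.

Mutation-efficiency arithmetic over regenerant/resistant clone counts,
Kruskal-Wallis comparisons of per-plant mutation counts between treatment
groups (exact permutation null for the tiny group sizes typical of this
design), Spearman correlation of per-chromosome variant counts against
chromosome length, and exact rational aggregation of the per-plant count
table into per-strategy means and totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 8
DEFAULT_ALPHA = 0.05


def mutation_efficiency(resistant: int, regenerants: int) -> float:
    """Relative mutation efficiency: % of resistant clones among
    regenerants, to 2 decimals."""
    if regenerants <= 0:
        raise ValueError("regenerants must be > 0")
    if not (0 <= resistant <= regenerants):
        raise ValueError("resistant must lie in [0, regenerants]")
    return round(100.0 * resistant / regenerants, 2)


def _h_statistic(ranks: Sequence[np.ndarray], n: int, tie_term: float) -> float:
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / len(r) for r in ranks) - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _tie_term(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n) if n > 1 else 1.0


def kruskal_exact(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with an exact permutation p-value.

    Enumerates every assignment of the pooled observations to the group
    sizes; p is the fraction of assignments with H at least the observed
    value (ties in the data are handled through midranks and the standard
    tie correction).  Intended for small designs (total n <= ~10).
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    tie = _tie_term(pooled)
    bounds = np.cumsum([0] + sizes)
    observed = _h_statistic(
        [ranks[bounds[i]:bounds[i + 1]] for i in range(len(sizes))], n, tie
    )
    ge = total = 0
    for perm in permutations(range(n)):
        rperm = ranks[list(perm)]
        h = _h_statistic(
            [rperm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))], n, tie
        )
        total += 1
        if h >= observed - 1e-12:
            ge += 1
    return observed, ge / total


@dataclass(frozen=True)
class GroupComparison:
    h: float
    p: float
    method: str  # "exact" | "asymptotic"
    alpha: float
    distinguishable: bool
    pairwise: dict


def group_count_comparison(
    groups: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = EXACT_MAX_N,
) -> GroupComparison:
    """Omnibus Kruskal-Wallis over per-plant counts, plus all pairwise
    contrasts.

    Uses the exact permutation null when the pooled size is at most
    ``exact_max_n`` (the asymptotic chi-square approximation is poor for
    the 2-5 plants per group this design has), the tie-corrected
    asymptotic test otherwise.  ``distinguishable`` flags p < alpha.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} has no plants")

    def one_test(subset: Sequence[str]) -> tuple[float, float, str]:
        data = [list(groups[g]) for g in subset]
        n = sum(len(d) for d in data)
        if len({v for d in data for v in d}) == 1:
            return 0.0, 1.0, "degenerate"
        if n <= exact_max_n:
            h, p = kruskal_exact(data)
            return h, p, "exact"
        h, p = sps.kruskal(*data)
        return float(h), float(p), "asymptotic"

    h, p, method = one_test(names)
    pairwise = {}
    for a, b in combinations(names, 2):
        ph, pp, pm = one_test([a, b])
        pairwise[(a, b)] = {
            "h": ph, "p": pp, "method": pm, "distinguishable": pp < alpha
        }
    return GroupComparison(
        h=h, p=p, method=method, alpha=alpha,
        distinguishable=p < alpha, pairwise=pairwise,
    )


def chromosome_length_correlation(
    per_chrom_counts: Sequence[float], chrom_lengths: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of per-chromosome variant counts against
    chromosome lengths: (rho, p)."""
    if len(per_chrom_counts) != len(chrom_lengths):
        raise ValueError("counts and lengths must have equal length")
    if len(per_chrom_counts) < 3:
        raise ValueError("need at least 3 chromosomes")
    res = sps.spearmanr(per_chrom_counts, chrom_lengths)
    return float(res.statistic), float(res.pvalue)


def headline_aggregates(counts: pd.DataFrame) -> dict:
    """Exact rational aggregation of a per-plant count table.

    Expects the columns produced by :func:`specaudit.classify.count_table`
    (``strategy``, ``n_snv``, ``n_indel``).  Returns per-strategy means of
    SNV and InDel counts (``None`` for empty strategies, never 0),
    per-strategy sums, and grand totals.  Means are exact fractions
    converted to float, so two-decimal reporting carries no rounding
    drift.
    """
    mean_snv: dict[str, float | None] = {}
    mean_indel: dict[str, float | None] = {}
    sum_snv: dict[str, int] = {}
    sum_indel: dict[str, int] = {}
    for strategy, sub in counts.groupby("strategy", sort=True):
        n = len(sub)
        s_snv = int(sub["n_snv"].sum())
        s_indel = int(sub["n_indel"].sum())
        sum_snv[strategy] = s_snv
        sum_indel[strategy] = s_indel
        mean_snv[strategy] = float(Fraction(s_snv, n)) if n else None
        mean_indel[strategy] = float(Fraction(s_indel, n)) if n else None
    total_snv = int(counts["n_snv"].sum())
    total_indel = int(counts["n_indel"].sum())
    return {
        "mean_snv": mean_snv,
        "mean_indel": mean_indel,
        "sum_snv": sum_snv,
        "sum_indel": sum_indel,
        "total_snv": total_snv,
        "total_indel": total_indel,
        "total": total_snv + total_indel,
    }


def per_chromosome_counts(
    classified: Sequence, chrom_names: Sequence[str]
) -> pd.Series:
    """Number of classified variants on each chromosome (Circos-style
    tabular summary)."""
    counts = pd.Series(0, index=list(chrom_names), dtype=int)
    for v in classified:
        if v.chrom in counts.index:
            counts[v.chrom] += 1
    return counts
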