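"""Efficiency arithmetic, rank tests and exact aggregation."""

from __future__ import annotations

import dataclasses
from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from specaudit import (
    SimulationConfig,
    chromosome_length_correlation,
    group_count_comparison,
    headline_aggregates,
    mutation_efficiency,
    simulate_experiment,
    simulate_reference,
)
from specaudit.simulate import study_scale_config
from specaudit.stats import kruskal_exact, per_chromosome_counts
from specaudit.study_design import PLANT_COUNTS


# ---------------------------------------------------------------------------
# mutation efficiency
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "resistant,regenerants,expected",
    [
        (56, 68_300, 0.08),     # TALEN row of the efficiency table
        (0, 1_000, 0.0),
        (1_718, 71_100, 2.42),  # pooled sgRNA#1 ratio (printed 2.41 is a
                                # mean of three experiments)
        (2_077, 61_600, 3.37),
    ],
)
def test_mutation_efficiency(resistant, regenerants, expected):
    assert mutation_efficiency(resistant, regenerants) == expected


def test_mutation_efficiency_input_validation():
    with pytest.raises(ValueError):
        mutation_efficiency(1, 0)
    with pytest.raises(ValueError):
        mutation_efficiency(5, 4)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_identical_counts_give_h_zero_p_one():
    res = group_count_comparison({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
    assert res.h == 0.0 and res.p == 1.0
    assert not res.distinguishable


def test_exact_p_matches_exhaustive_rank_permutation_oracle():
    groups = {"low": [1, 2], "high": [100, 101], "mid": [50, 51]}
    res = group_count_comparison(groups, alpha=0.1)
    assert res.method == "exact"

    # independent oracle: permute the 6 values over the group slots and
    # count permutations with a Kruskal-Wallis H at least the observed one
    values = [1, 2, 100, 101, 50, 51]
    h_obs = sps.kruskal([1, 2], [100, 101], [50, 51]).statistic
    ge = total = 0
    for perm in permutations(values):
        h = sps.kruskal(list(perm[:2]), list(perm[2:4]), list(perm[4:])).statistic
        total += 1
        ge += h >= h_obs - 1e-12
    assert res.p == pytest.approx(ge / total)
    # perfectly separated groups: exact p is 3!/(6!/(2!2!2!)) = 1/15
    assert res.p == pytest.approx(1 / 15)
    assert res.h == pytest.approx(h_obs)
    assert res.distinguishable  # at the configured alpha of 0.1


def test_exact_h_agrees_with_scipy_on_ties():
    groups = [[1, 2, 2], [2, 3, 4]]
    h, _ = kruskal_exact(groups)
    assert h == pytest.approx(sps.kruskal(*groups).statistic)


def test_group_labelling_order_is_irrelevant():
    a = group_count_comparison({"x": [1, 5, 3], "y": [9, 7, 8]})
    b = group_count_comparison({"y": [9, 7, 8], "x": [1, 5, 3]})
    assert a.h == pytest.approx(b.h) and a.p == pytest.approx(b.p)


def test_large_samples_fall_back_to_asymptotic():
    groups = {"a": list(range(10)), "b": list(range(5, 15))}
    res = group_count_comparison(groups)
    assert res.method == "asymptotic"
    h, p = sps.kruskal(groups["a"], groups["b"])
    assert res.h == pytest.approx(h) and res.p == pytest.approx(p)


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        group_count_comparison({"a": [1], "b": []})


def test_equal_induced_rates_are_rarely_distinguishable():
    """PEG-only vs edited plants with identical mutagenic exposure should
    pass the omnibus test (alpha 0.05) in >= 90% of runs."""
    base = study_scale_config(with_planted_offtarget=False)
    base = dataclasses.replace(
        base,
        chrom_lengths=(30_000, 20_000, 10_000),
        n_ref_polymorphisms=20, n_lineage_polymorphisms=5,
        noise_rate=0.0, peg_snv_mean=8.0, peg_indel_mean=8.0,
    )
    genome = simulate_reference(base)
    not_distinguishable = 0
    for seed in range(100):
        cfg = dataclasses.replace(base, seed=seed)
        truth = simulate_experiment(cfg, genome).truth
        induced = truth[truth.category == "treatment_induced"]
        peg = [int((induced.sample_id == p).sum())
               for p in ("PEG#1", "PEG#2", "PEG-DNA#1")]
        edited = [int((induced.sample_id == p).sum())
                  for p in ("CRIS1#1", "CRIS1#2", "CRIS2#1", "CRIS2#2",
                            "TAL#1", "TAL#2")]
        res = group_count_comparison({"peg": peg, "edited": edited})
        not_distinguishable += not res.distinguishable
    assert not_distinguishable >= 90


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def test_monotone_counts_give_rho_plus_minus_one():
    lengths = [10, 20, 30, 40]
    assert chromosome_length_correlation([1, 2, 3, 4], lengths)[0] == 1.0
    assert chromosome_length_correlation([4, 3, 2, 1], lengths)[0] == -1.0


def test_spearman_matches_rank_formula_oracle():
    rng = np.random.default_rng(5)
    counts = rng.permutation(np.arange(1, 9)).tolist()
    lengths = rng.permutation(np.arange(10, 18)).tolist()
    rho, _ = chromosome_length_correlation(counts, lengths)
    # hand formula (no ties): rho = 1 - 6*sum(d^2)/(n(n^2-1))
    rc = sps.rankdata(counts)
    rl = sps.rankdata(lengths)
    d2 = float(((rc - rl) ** 2).sum())
    assert rho == pytest.approx(1 - 6 * d2 / (8 * 63))


def test_too_few_chromosomes_is_an_error():
    with pytest.raises(ValueError):
        chromosome_length_correlation([1, 2], [10, 20])


def test_length_correlation_is_significant_at_study_scale_counts():
    """With study-scale variant numbers spread over ten chromosomes, the
    count/length correlation should be positive and significant in >= 95%
    of seeded runs."""
    lengths = tuple(range(10_000, 110_000, 10_000))
    hits = 0
    for seed in range(20):
        cfg = SimulationConfig(
            chrom_lengths=lengths, n_ref_polymorphisms=600,
            n_lineage_polymorphisms=0, noise_rate=0.0, seed=seed,
        )
        genome = simulate_reference(cfg)
        result = simulate_experiment(cfg, genome)
        counts = [sum(r.chrom == f"chr{i + 1}" for r in result.records)
                  for i in range(len(lengths))]
        rho, p = chromosome_length_correlation(counts, list(lengths))
        hits += (rho > 0) and (p < 0.05)
    assert hits >= 19


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_headline_aggregates_on_published_count_table():
    agg = headline_aggregates(PLANT_COUNTS)
    assert agg["mean_snv"]["crispr"] == 8.25
    assert agg["mean_indel"]["crispr"] == 19.5
    assert agg["mean_indel"]["talen"] == 32
    assert agg["mean_snv"]["talen"] == 16  # computed from the per-plant cells
    assert agg["sum_snv"]["peg"] == 30 and agg["sum_indel"]["peg"] == 38


def test_empty_strategy_mean_is_undefined_not_zero():
    import pandas as pd

    counts = pd.DataFrame({"strategy": [], "n_snv": [], "n_indel": []})
    agg = headline_aggregates(counts)
    assert agg["mean_snv"] == {} and agg["total"] == 0


def test_per_chromosome_counts_helper():
    class V:
        def __init__(self, chrom):
            self.chrom = chrom

    counts = per_chromosome_counts([V("chr1"), V("chr1"), V("chr2")],
                                   ["chr1", "chr2", "chr3"])
    assert counts.tolist() == [2, 1, 0]
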