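"""Mismatch-tolerant site search, TALEN pairing, and interval crossing."""

from __future__ import annotations

import numpy as np
import pytest

from specaudit import (
    GenomeSequence,
    NucleaseSpec,
    VariantCall,
    find_approximate_matches,
    intersect_sites_with_variants,
    pair_talen_sites,
    predict_crispr_offtargets,
    predict_talen_offtargets,
)
from specaudit.offtargets import revcomp
from specaudit.simulate import plant_target_locus

from conftest import (
    brute_force_matches,
    brute_force_pairs,
    hits_as_tuples,
    make_hit,
    random_genome,
)

QUERY = "GACGTTACCGGATTGCCATGTGG"  # 23 nt


def _embed(seq: str, insert: str, at: int) -> str:
    return seq[:at] + insert + seq[at + len(insert):]


def test_exact_copy_found_once_on_plus_strand():
    g = random_genome(5, 4000)
    seq = _embed(g[0].seq, QUERY, 1200)
    genome = [GenomeSequence("chr1", seq)]
    hits = find_approximate_matches(genome, QUERY, 0)
    assert [(h.start, h.strand, h.mismatches) for h in hits] == [(1200, "+", 0)]


def test_reverse_complement_copy_reported_on_minus_strand():
    g = random_genome(6, 4000)
    seq = _embed(g[0].seq, revcomp(QUERY), 800)
    hits = find_approximate_matches([GenomeSequence("chr1", seq)], QUERY, 0)
    assert [(h.start, h.end, h.strand) for h in hits] == [(800, 800 + 23, "-")]


def test_n_bases_count_as_mismatches():
    seq = "T" * 50 + QUERY + "T" * 50
    seq = _embed(seq, "NN", 50)  # two Ns inside the copy
    hits = find_approximate_matches([GenomeSequence("chr1", seq)], QUERY, 5)
    assert len(hits) == 1 and hits[0].mismatches == 2
    assert find_approximate_matches([GenomeSequence("chr1", seq)], QUERY, 1) == []


@pytest.mark.parametrize("seed", [42, 43, 44])
def test_matches_equal_brute_force_oracle(seed):
    genome = random_genome(seed, 10_000)
    rng = np.random.default_rng(seed + 1000)
    query = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=23)])
    hits = find_approximate_matches(genome, query, 5)
    assert hits_as_tuples(hits) == brute_force_matches(genome, query, 5)


def test_hit_set_grows_monotonically_with_mismatch_budget():
    genome = random_genome(9, 20_000)
    prev: set = set()
    for k in range(0, 7):
        cur = hits_as_tuples(
            h for h in find_approximate_matches(genome, QUERY, k)
        )
        cur_loci = {t[:4] for t in cur}
        assert {t[:4] for t in prev} <= cur_loci
        prev = cur


def test_strand_symmetry_of_search():
    genome = random_genome(12, 15_000)
    fwd = find_approximate_matches(genome, QUERY, 5)
    rev = find_approximate_matches(genome, revcomp(QUERY), 5)
    flip = {"+": "-", "-": "+"}
    assert {(h.chrom, h.start, h.end, flip[h.strand], h.mismatches) for h in fwd} == \
        hits_as_tuples(rev)


def test_no_hits_when_no_copy_present():
    # genome over a two-letter alphabet can never be within 5 mm of QUERY
    genome = [GenomeSequence("chr1", "AC" * 5000)]
    assert find_approximate_matches(genome, QUERY, 0) == []


# ---------------------------------------------------------------------------
# CRISPR prediction
# ---------------------------------------------------------------------------


def _mutate(seq: str, n: int, rng) -> str:
    out = list(seq)
    for i in rng.choice(len(out), size=n, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def test_planted_degenerate_copies_counted_by_mismatch_budget(specs):
    spec = specs[0]
    genome = random_genome(21, 30_000)
    genome = plant_target_locus(genome, spec, "chr1", 10_000)
    rng = np.random.default_rng(0)
    seq = genome[0].seq
    for n_mm, at in ((2, 2000), (4, 4000), (6, 6000)):
        seq = _embed(seq, _mutate(spec.query, n_mm, rng), at)
    genome = [GenomeSequence("chr1", seq)]
    hits = predict_crispr_offtargets(genome, spec)
    on = [h for h in hits if h.is_on_target]
    off = [h for h in hits if not h.is_on_target]
    assert len(on) == 1 and on[0].mismatches == 0
    assert sorted(h.mismatches for h in off) == [2, 4]  # 6-mm copy excluded
    assert hits_as_tuples(hits) == brute_force_matches(genome, spec.query, 5)


def test_pam_aware_mode_requires_ngg(specs):
    spec = specs[0]  # PAM TGG
    base = "T" * 300
    proto = spec.protospacer
    seq = _embed(base, proto + "AGG", 40)     # NGG, should hit
    seq = _embed(seq, proto + "ATT", 120)     # no PAM, must not hit
    seq = _embed(seq, "CC" + "A" + revcomp(proto), 200)  # minus-strand NGG
    genome = [GenomeSequence("chr1", seq)]
    hits = predict_crispr_offtargets(genome, spec, pam_aware=True)
    assert {(h.start, h.strand) for h in hits} == {(40, "+"), (200, "-")}
    assert all(h.mismatches == 0 for h in hits)


# ---------------------------------------------------------------------------
# TALEN pairing
# ---------------------------------------------------------------------------


def test_single_facing_pair_with_gap_20():
    left = make_hit("chr1", 1000, 1018, "+")
    right = make_hit("chr1", 1038, 1056, "-")  # gap = 20
    pairs = pair_talen_sites([left], [right], 5, 50)
    assert [(p.start, p.end) for p in pairs] == [(1000, 1056)]


@pytest.mark.parametrize("gap,expected", [(4, 0), (5, 1), (50, 1), (51, 0)])
def test_spacer_boundaries_are_inclusive_5_to_50(gap, expected):
    left = make_hit("chr1", 100, 118, "+")
    right = make_hit("chr1", 118 + gap, 136 + gap, "-")
    assert len(pair_talen_sites([left], [right], 5, 50)) == expected


def test_non_facing_orientations_do_not_pair():
    a = make_hit("chr1", 100, 118, "-")
    b = make_hit("chr1", 130, 148, "+")
    assert pair_talen_sites([a], [b], 5, 50) == []


def test_pairing_equals_brute_force_over_random_placements():
    rng = np.random.default_rng(77)
    hits = [
        make_hit(
            f"chr{rng.integers(1, 3)}",
            int(start := rng.integers(0, 5000)),
            int(start) + 18,
            "+" if rng.random() < 0.5 else "-",
            int(rng.integers(0, 6)),
        )
        for _ in range(50)
    ]
    half = len(hits) // 2
    pairs = pair_talen_sites(hits[:half], hits[half:], 5, 50)
    assert {(p.chrom, p.start, p.end) for p in pairs} == \
        brute_force_pairs(hits, 5, 50)


def test_planted_talen_locus_yields_exactly_one_pair(specs):
    spec = specs[2]
    spec.max_mismatches = 0  # exact-match self-recovery of the planted pair
    genome = random_genome(31, 30_000)
    genome = plant_target_locus(genome, spec, "chr1", 9_000)
    pairs = predict_talen_offtargets(genome, spec)
    assert len(pairs) == 1
    assert pairs[0].is_on_target and pairs[0].mismatches == 0
    assert (pairs[0].start, pairs[0].end) == (9_000, 9_000 + 17 + 16 + 17)


# ---------------------------------------------------------------------------
# site x variant intersection
# ---------------------------------------------------------------------------


def _var(chrom: str, pos: int) -> VariantCall:
    return VariantCall(chrom, pos, "A", "T", 60.0, 20, 20, "s1")


def test_intersection_window_boundary():
    site = make_hit("chr1", 100, 123, "+")
    inside = _var("chr1", 110)
    outside = _var("chr1", 133)  # 10 bp past the end
    assert intersect_sites_with_variants([site], [inside], 0) == [(site, inside)]
    assert intersect_sites_with_variants([site], [outside], 10) == [(site, outside)]
    assert intersect_sites_with_variants([site], [outside], 9) == []


def test_intersection_equals_all_pairs_oracle():
    rng = np.random.default_rng(4)
    sites = [
        make_hit(f"chr{rng.integers(1, 4)}", int(s := rng.integers(0, 3000)),
                 int(s) + int(rng.integers(10, 60)), "+")
        for _ in range(40)
    ]
    variants = [
        _var(f"chr{rng.integers(1, 4)}", int(rng.integers(1, 3000)))
        for _ in range(60)
    ]
    got = intersect_sites_with_variants(sites, variants, 25)
    expected = [
        (s, v)
        for v in variants
        for s in sites
        if s.chrom == v.chrom and v.pos - 1 < s.end + 25 and v.pos > s.start - 25
    ]
    assert {(id(s), id(v)) for s, v in got} == {(id(s), id(v)) for s, v in expected}
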