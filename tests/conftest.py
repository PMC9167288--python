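"""Shared fixtures: small synthetic configs and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from specaudit import NucleaseSpec, SimulationConfig
from specaudit.offtargets import OffTargetSite, revcomp


def make_specs() -> tuple[NucleaseSpec, ...]:
    """Fresh nuclease specs (mutable: planting fills in the loci)."""
    return (
        NucleaseSpec("sgRNA1", "crispr",
                     protospacer="GACGTTACCGGATTGCCATG", pam="TGG"),
        NucleaseSpec("sgRNA2", "crispr",
                     protospacer="TTCAGGCTAAGCGTATACCA", pam="AGG"),
        NucleaseSpec("talen1", "talen",
                     left_site="TCCTGAGGACAAGTCAC", right_site="TGGACCTTAGACAAGTA"),
    )


@pytest.fixture
def specs() -> tuple[NucleaseSpec, ...]:
    return make_specs()


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast, group-C-only experiment (no nucleases)."""
    return SimulationConfig(
        chrom_lengths=(20_000, 15_000, 10_000),
        n_ref_polymorphisms=40,
        n_lineage_polymorphisms=15,
        noise_rate=5.0,
        seed=11,
    )


def random_genome(seed: int, length: int = 10_000, n_chroms: int = 1) -> list:
    from specaudit import GenomeSequence

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return [
        GenomeSequence(f"chr{i + 1}", "".join(bases[rng.integers(0, 4, size=length)]))
        for i in range(n_chroms)
    ]


# ---------------------------------------------------------------------------
# independent oracles (naive, string-based)
# ---------------------------------------------------------------------------


def brute_force_matches(genome, query: str, max_mm: int) -> set[tuple]:
    """Sliding-window Hamming scan over both strands, one window at a time."""
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for g in genome:
            seq = g.seq
            for i in range(len(seq) - len(q) + 1):
                mm = sum(1 for a, b in zip(seq[i:i + len(q)], q) if a != b)
                if mm <= max_mm:
                    out.add((g.name, i, i + len(q), strand, mm))
    return out


def brute_force_pairs(hits, spacer_min: int, spacer_max: int) -> set[tuple]:
    """All-pairs double loop over half-site hits."""
    out = set()
    for a in hits:
        for b in hits:
            if (
                a.chrom == b.chrom
                and a.strand == "+"
                and b.strand == "-"
                and spacer_min <= b.start - a.end <= spacer_max
            ):
                out.add((a.chrom, a.start, b.end))
    return out


def hits_as_tuples(hits) -> set[tuple]:
    return {(h.chrom, h.start, h.end, h.strand, h.mismatches) for h in hits}


def make_hit(chrom: str, start: int, end: int, strand: str, mm: int = 0) -> OffTargetSite:
    return OffTargetSite(chrom=chrom, start=start, end=end, strand=strand,
                         mismatches=mm)
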