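"""Homology-based prediction of candidate nuclease cleavage sites.

A CRISPR guide is searched as its full protospacer+PAM query with a
Hamming-distance tolerance (default 5 mismatches) over both strands of the
genome; TALEN half-sites are searched the same way and then paired in
facing orientation under a FokI spacer constraint (default 5-50 bp gap).
Matching is ungapped; ``N`` reference bases never match any query base.

Predicted sites are intersected with observed variant calls to flag
candidate off-target mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import GenomeSequence, VariantCall, genome_dict

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# A/C/G/T -> 0..3; every other byte (incl. N) keeps its ASCII code and can
# never equal an encoded query base, so N counts as a mismatch.
_ENCODE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_ENCODE), dtype=np.uint8)


@dataclass
class NucleaseSpec:
    """A CRISPR guide (protospacer + PAM) or a TALEN half-site pair.

    ``on_target`` and ``cut_site`` use 0-based half-open genome coordinates
    and are filled in when the target locus is known (e.g. after planting
    it into a synthetic genome).
    """

    nuclease_id: str
    kind: str  # "crispr" | "talen"
    protospacer: str = ""
    pam: str = ""
    left_site: str = ""
    right_site: str = ""
    spacer_min: int = 5
    spacer_max: int = 50
    max_mismatches: int = 5
    on_target: tuple[str, int, int] | None = None  # (chrom, start, end)
    cut_site: tuple[str, int] | None = None  # (chrom, pos)

    def __post_init__(self) -> None:
        if self.kind not in {"crispr", "talen"}:
            raise ValueError(f"unknown nuclease kind {self.kind!r}")
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min > spacer_max")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for seq in (self.protospacer, self.pam, self.left_site, self.right_site):
            if seq and set(seq) - set("ACGT"):
                raise ValueError(f"nuclease sequence {seq!r} not over ACGT")
        if self.kind == "crispr" and not self.protospacer:
            raise ValueError("crispr spec needs a protospacer")
        if self.kind == "talen" and not (self.left_site and self.right_site):
            raise ValueError("talen spec needs left and right half-sites")

    @property
    def query(self) -> str:
        """Full CRISPR query sequence (protospacer followed by PAM)."""
        return self.protospacer + self.pam


@dataclass(frozen=True, order=True)
class OffTargetSite:
    """A genomic locus predicted as cleavable (0-based half-open span).

    For TALEN pairs the span runs from the upstream half-site through the
    downstream one and ``mismatches`` is the summed half-site mismatch
    count.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    nuclease_id: str | None = None
    is_on_target: bool = False

    def overlaps(self, chrom: str, start: int, end: int, pad: int = 0) -> bool:
        return (
            chrom == self.chrom and start < self.end + pad and end > self.start - pad
        )


# ---------------------------------------------------------------------------
# approximate matching
# ---------------------------------------------------------------------------


def find_approximate_matches(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    query: str,
    max_mm: int,
    nuclease_id: str | None = None,
) -> list[OffTargetSite]:
    """All ungapped alignments of ``query`` within ``max_mm`` mismatches.

    Both strands are scanned; a reverse-strand hit is reported with the
    coordinates of its plus-strand window.  Output is sorted by
    (chrom, start, strand) and each window/strand appears at most once.
    """
    query = query.upper()
    if len(query) < 10:
        raise ValueError("query shorter than 10 nt")
    if max_mm >= len(query):
        raise ValueError("max_mm must be smaller than the query length")
    if set(query) - set("ACGT"):
        raise ValueError("query must be over ACGT")

    q_fwd = _encode(query)
    q_rev = _encode(revcomp(query))
    L = len(query)
    hits: list[OffTargetSite] = []
    for name, seq in genome_dict(genome).items():
        if len(seq) < L:
            continue
        windows = sliding_window_view(_encode(seq), L)
        for q, strand in ((q_fwd, "+"), (q_rev, "-")):
            mm = (windows != q).sum(axis=1)
            for start in np.nonzero(mm <= max_mm)[0]:
                hits.append(
                    OffTargetSite(
                        chrom=name,
                        start=int(start),
                        end=int(start) + L,
                        strand=strand,
                        mismatches=int(mm[start]),
                        nuclease_id=nuclease_id,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _pam_aware_matches(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
) -> list[OffTargetSite]:
    """NGG-requiring scan: mismatches counted over the 20-nt protospacer
    only; the window must end in a canonical NGG PAM (strand-aware)."""
    proto = spec.protospacer
    L = len(proto) + 3
    p_fwd = _encode(proto)
    p_rev = _encode(revcomp(proto))
    G = _encode("G")[0]
    C = _encode("C")[0]
    hits: list[OffTargetSite] = []
    for name, seq in genome_dict(genome).items():
        if len(seq) < L:
            continue
        windows = sliding_window_view(_encode(seq), L)
        # plus strand: [proto][N G G]
        mm = (windows[:, : len(proto)] != p_fwd).sum(axis=1)
        ok = (mm <= spec.max_mismatches) & (windows[:, -2] == G) & (windows[:, -1] == G)
        for start in np.nonzero(ok)[0]:
            hits.append(
                OffTargetSite(name, int(start), int(start) + L, "+", int(mm[start]),
                              spec.nuclease_id)
            )
        # minus strand: plus-strand window reads [C C N][revcomp(proto)]
        mm = (windows[:, 3:] != p_rev).sum(axis=1)
        ok = (mm <= spec.max_mismatches) & (windows[:, 0] == C) & (windows[:, 1] == C)
        for start in np.nonzero(ok)[0]:
            hits.append(
                OffTargetSite(name, int(start), int(start) + L, "-", int(mm[start]),
                              spec.nuclease_id)
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def predict_crispr_offtargets(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
    pam_aware: bool = False,
) -> list[OffTargetSite]:
    """Candidate cleavage sites for a CRISPR guide.

    Default mode searches the full protospacer+PAM query with mismatches
    counted uniformly over all positions; ``pam_aware`` instead requires a
    canonical NGG and counts mismatches over the protospacer only.  Hits
    overlapping the declared on-target locus are flagged.
    """
    if spec.kind != "crispr":
        raise ValueError("spec is not a crispr nuclease")
    if pam_aware:
        hits = _pam_aware_matches(genome, spec)
    else:
        hits = find_approximate_matches(
            genome, spec.query, spec.max_mismatches, spec.nuclease_id
        )
    return _flag_on_target(hits, spec)


def predict_talen_offtargets(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
) -> list[OffTargetSite]:
    """Candidate paired TALEN sites under the spacer constraint."""
    if spec.kind != "talen":
        raise ValueError("spec is not a talen nuclease")
    left = find_approximate_matches(genome, spec.left_site, spec.max_mismatches,
                                    spec.nuclease_id)
    right = find_approximate_matches(genome, spec.right_site, spec.max_mismatches,
                                     spec.nuclease_id)
    pairs = pair_talen_sites(left, right, spec.spacer_min, spec.spacer_max,
                             spec.nuclease_id)
    return _flag_on_target(pairs, spec)


def _flag_on_target(hits: list[OffTargetSite], spec: NucleaseSpec) -> list[OffTargetSite]:
    if spec.on_target is None:
        return hits
    chrom, start, end = spec.on_target
    flagged = [
        replace(h, is_on_target=True) if h.overlaps(chrom, start, end) else h
        for h in hits
    ]
    if not any(h.is_on_target for h in flagged):
        logger.warning(
            "no hit of %s overlaps its declared on-target locus %s:%d-%d",
            spec.nuclease_id, chrom, start, end,
        )
    return flagged


def pair_talen_sites(
    left_hits: Sequence[OffTargetSite],
    right_hits: Sequence[OffTargetSite],
    spacer_min: int,
    spacer_max: int,
    nuclease_id: str | None = None,
) -> list[OffTargetSite]:
    """Facing half-site pairs whose inner gap lies within the spacer range.

    A qualifying pair has the upstream half-site bound on the plus strand
    and the downstream one on the minus strand, with
    ``spacer_min <= gap <= spacer_max`` measured between the facing inner
    edges.  All four identity combinations (left/left, left/right,
    right/left, right/right) are considered; each genomic pair is reported
    once with summed half-site mismatches.
    """
    all_hits = list(left_hits) + list(right_hits)
    plus = [h for h in all_hits if h.strand == "+"]
    minus = [h for h in all_hits if h.strand == "-"]
    seen: set[tuple[str, int, int]] = set()
    pairs: list[OffTargetSite] = []
    for up in plus:
        for down in minus:
            if up.chrom != down.chrom:
                continue
            gap = down.start - up.end
            if not (spacer_min <= gap <= spacer_max):
                continue
            key = (up.chrom, up.start, down.end)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                OffTargetSite(
                    chrom=up.chrom,
                    start=up.start,
                    end=down.end,
                    strand="+",
                    mismatches=up.mismatches + down.mismatches,
                    nuclease_id=nuclease_id,
                )
            )
    pairs.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return pairs


def intersect_sites_with_variants(
    sites: Sequence[OffTargetSite],
    variants: Sequence[VariantCall],
    window_bp: int = 50,
) -> list[tuple[OffTargetSite, VariantCall]]:
    """All (site, variant) pairs where the variant's reference span falls
    within the site span extended by ``window_bp`` on each side."""
    by_chrom: dict[str, list[OffTargetSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[tuple[OffTargetSite, VariantCall]] = []
    for v in variants:
        vstart = v.pos - 1
        vend = vstart + len(v.ref)
        for s in by_chrom.get(v.chrom, ()):
            if vstart < s.end + window_bp and vend > s.start - window_bp:
                out.append((s, v))
    return out
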