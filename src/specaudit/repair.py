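"""Repair-pathway signatures of on-target indels.

Alternative end joining (Alt-EJ/MMEJ) repairs a double-strand break by
annealing microhomologies that flank the cut, deleting one copy of the
repeat together with the intervening sequence.  Such deletions leave a
junction microhomology that this module measures; deletions with a
sufficient junction microhomology are Alt-EJ-compatible, deletions whose
junction carries a single extra base substitution are Alt-EJ with
substitution, and insertions or microhomology-free indels look like
classical non-homologous end joining (C-NHEJ).
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_MIN_MH = 2

ALT_EJ = "alt_ej_compatible"
ALT_EJ_SUB = "alt_ej_with_substitution"
C_NHEJ = "c_nhej_like"


@dataclass(frozen=True)
class MicrohomologyCall:
    chrom: str
    start: int  # deleted span, 0-based half-open (insertions: cut position)
    end: int
    mh_length: int
    repair_class: str
    substitutions: int


def max_microhomology(ref_sequence: str, deleted_span: tuple[int, int]) -> int:
    """Maximal junction microhomology of a deletion, in bases.

    Returns the largest ``m`` such that the ``m`` bases immediately before
    the deleted span equal the last ``m`` bases of the span, or the first
    ``m`` bases of the span equal the ``m`` bases immediately after it
    (the two representations of a microhomology-collapsing deletion are
    equivalent, so both junction alignments are checked).  Capped at the
    deletion length.
    """
    s, e = deleted_span
    d = e - s
    if d <= 0:
        raise ValueError("deleted span must be non-empty")
    if s <= 0 or e >= len(ref_sequence):
        raise ValueError("deleted span needs flanking sequence on both sides")

    # left alignment: suffix of the upstream flank vs. suffix of the span
    m_left = 0
    while m_left < min(d, s) and ref_sequence[s - 1 - m_left] == ref_sequence[e - 1 - m_left]:
        m_left += 1
    # right alignment: prefix of the span vs. prefix of the downstream flank
    m_right = 0
    limit = min(d, len(ref_sequence) - e)
    while m_right < limit and ref_sequence[s + m_right] == ref_sequence[e + m_right]:
        m_right += 1
    return max(m_left, m_right)


def _best_decompositions(ref: str, alt: str) -> tuple[list[int], int]:
    """Decompose a net-deletion variant into one contiguous deleted block
    plus junction substitutions.

    Tries every placement of the deleted block within ``ref`` and returns
    (offsets of the block within ref, substitution count) for the
    placements needing the fewest substitutions in the retained sequence.
    """
    d = len(ref) - len(alt)
    by_subs: dict[int, list[int]] = {}
    for i in range(len(alt) + 1):
        remaining = ref[:i] + ref[i + d:]
        subs = sum(a != b for a, b in zip(remaining, alt))
        by_subs.setdefault(subs, []).append(i)
    best = min(by_subs)
    return by_subs[best], best


def classify_repair(variant, ref_sequence: str, min_mh: int = DEFAULT_MIN_MH) -> MicrohomologyCall:
    """Assign a repair-pathway class to an on-target indel.

    ``variant`` needs ``chrom``/``pos`` (1-based)/``ref``/``alt``
    attributes; ``ref_sequence`` is the chromosome the variant lies on.
    Pure deletions with junction microhomology >= ``min_mh`` are
    Alt-EJ-compatible; net deletions that additionally carry exactly one
    junction substitution (complex indels are decomposed first) are Alt-EJ
    with substitution; insertions and everything else are C-NHEJ-like.
    """
    ref, alt = variant.ref, variant.alt
    if min_mh < 1:
        raise ValueError("min_mh must be >= 1")
    if len(ref) == 1 and len(alt) == 1:
        raise ValueError("classify_repair expects an indel, got an SNV")

    start0 = variant.pos - 1
    if len(alt) >= len(ref):
        # net insertion (or length-preserving complex event)
        return MicrohomologyCall(
            chrom=variant.chrom, start=start0, end=start0 + len(ref),
            mh_length=0, repair_class=C_NHEJ, substitutions=0,
        )

    if ref_sequence[start0:start0 + len(ref)] != ref:
        raise ValueError(
            f"variant ref allele does not match the genome at "
            f"{variant.chrom}:{variant.pos}"
        )
    d = len(ref) - len(alt)
    offsets, subs = _best_decompositions(ref, alt)
    # equivalent placements of the deleted block: keep the one with the
    # largest junction microhomology (leftmost on ties)
    s, e, mh = -1, -1, -1
    for offset in offsets:
        cand_s = start0 + offset
        cand_mh = max_microhomology(ref_sequence, (cand_s, cand_s + d))
        if cand_mh > mh:
            s, e, mh = cand_s, cand_s + d, cand_mh
    if mh >= min_mh and subs == 0:
        repair_class = ALT_EJ
    elif mh >= min_mh and subs == 1:
        repair_class = ALT_EJ_SUB
    else:
        repair_class = C_NHEJ
    return MicrohomologyCall(
        chrom=variant.chrom, start=s, end=e,
        mh_length=mh, repair_class=repair_class, substitutions=subs,
    )
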