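"""Lineage-aware attribution of variants in a clonal haploid experiment.

Every classifiable site is assigned exactly one category by an explicit
precedence (first rule that matches wins):

1. fixed in all non-excluded samples        -> ``ref_polymorphism``
2. fixed in one wild type and all plants
   derived from it, absent elsewhere        -> ``lineage_polymorphism``
3. carried by an edited plant inside its
   nuclease's on-target window              -> ``on_target``
4. carried by an edited plant near a
   predicted off-target site of its
   nuclease                                 -> ``predicted_off_target_hit``
5. shared by >=2 independently regenerated
   plants, or fixed in a plant and subclonal
   in its wild type, or carried by an
   untreated control                        -> ``spontaneous``
6. carried only by PEG-exposed plants       -> ``treatment_associated``
7. anything else                            -> ``unattributed``

"Carried" means fixed (allele fraction >= 0.8); chimeric states act only
as attribution evidence and never enter per-plant counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import PEG_EXPOSED_ROLES, SampleMeta
from .offtargets import NucleaseSpec, OffTargetSite
from .pipeline import STATE_CHIMERIC, STATE_FIXED, VariantMatrix

CATEGORIES = [
    "ref_polymorphism",
    "lineage_polymorphism",
    "on_target",
    "predicted_off_target_hit",
    "spontaneous",
    "treatment_associated",
    "unattributed",
]
#: categories counted per plant against its matched wild type
MUTATION_CATEGORIES = CATEGORIES[2:]

DEFAULT_ON_TARGET_PAD = 50


@dataclass(frozen=True)
class ClassifiedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str
    size_class: str
    category: str
    carriers: tuple[str, ...]
    evidence: str

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def on_target_windows(
    specs: Sequence[NucleaseSpec], pad: int = DEFAULT_ON_TARGET_PAD
) -> dict[str, tuple[str, int, int]]:
    """Per-nuclease on-target window: the target span padded by ``pad`` bp
    on each side (covers microhomology-deletion spread around the cut)."""
    windows = {}
    for spec in specs:
        if spec.on_target is None:
            raise ValueError(f"nuclease {spec.nuclease_id} has no on_target locus")
        chrom, start, end = spec.on_target
        windows[spec.nuclease_id] = (chrom, max(0, start - pad), end + pad)
    return windows


def _span_in_window(
    chrom: str, start: int, end: int, window: tuple[str, int, int]
) -> bool:
    wchrom, wstart, wend = window
    return chrom == wchrom and start < wend and end > wstart


def classify_variants(
    matrix: VariantMatrix,
    metadata: Sequence[SampleMeta],
    windows: Mapping[str, tuple[str, int, int]],
    predicted_sites: Sequence[OffTargetSite] = (),
    window_bp: int = 50,
) -> list[ClassifiedVariant]:
    """Run the attribution decision tree over every classifiable site."""
    meta = {m.sample_id: m for m in metadata if not m.excluded}
    all_samples = set(matrix.samples)
    groups: dict[str, set[str]] = {}
    for m in meta.values():
        groups.setdefault(m.experiment_group, set()).add(m.sample_id)
    for m in meta.values():
        if m.role == "edited" and m.nuclease_id is None:
            raise ValueError(f"edited plant {m.sample_id} has no nuclease_id")

    offtarget_by_nuclease: dict[str, list[OffTargetSite]] = {}
    for s in predicted_sites:
        if not s.is_on_target and s.nuclease_id is not None:
            offtarget_by_nuclease.setdefault(s.nuclease_id, []).append(s)

    out: list[ClassifiedVariant] = []
    for sid, site in matrix.sites.iterrows():
        states = matrix.states.loc[sid]
        fixed = {s for s in matrix.samples if states[s] == STATE_FIXED}
        chimeric = {s for s in matrix.samples if states[s] == STATE_CHIMERIC}
        chrom, pos = site["chrom"], int(site["pos"])
        vstart, vend = pos - 1, pos - 1 + len(site["ref"])

        category, evidence = _decide(
            fixed, chimeric, all_samples, groups, meta,
            chrom, vstart, vend, windows, offtarget_by_nuclease, window_bp,
        )
        out.append(
            ClassifiedVariant(
                chrom=chrom, pos=pos, ref=site["ref"], alt=site["alt"],
                var_type=site["var_type"], size_class=site["size_class"],
                category=category, carriers=tuple(sorted(fixed)), evidence=evidence,
            )
        )
    return out


def _decide(
    fixed: set[str],
    chimeric: set[str],
    all_samples: set[str],
    groups: dict[str, set[str]],
    meta: dict[str, SampleMeta],
    chrom: str,
    vstart: int,
    vend: int,
    windows: Mapping[str, tuple[str, int, int]],
    offtargets: Mapping[str, list[OffTargetSite]],
    window_bp: int,
) -> tuple[str, str]:
    # 1. shared by everyone: divergence from the reference assembly
    if fixed == all_samples:
        return "ref_polymorphism", "fixed-in-all"
    # 2. fixed throughout exactly one wild-type pedigree
    for group, members in sorted(groups.items()):
        if fixed == members:
            return "lineage_polymorphism", f"lineage:{group}"
    edited_carriers = [s for s in sorted(fixed) if meta[s].role == "edited"]
    # 3. on-target edit of a carrier's nuclease
    for s in edited_carriers:
        window = windows.get(meta[s].nuclease_id)
        if window and _span_in_window(chrom, vstart, vend, window):
            return "on_target", f"on-target:{meta[s].nuclease_id}"
    # 4. near a predicted off-target site of a carrier's nuclease
    for s in edited_carriers:
        for site in offtargets.get(meta[s].nuclease_id, ()):
            if site.overlaps(chrom, vstart, vend, pad=window_bp):
                return (
                    "predicted_off_target_hit",
                    f"offtarget:{meta[s].nuclease_id}:{site.chrom}:{site.start}",
                )
    # 5. spontaneous: independent sharing, subclonal echo in the wild type,
    #    or presence in an untreated control
    nonwt = [s for s in fixed if meta[s].role != "wildtype"]
    for group, members in sorted(groups.items()):
        if len(fixed & members) >= 2 and len([s for s in fixed & members
                                              if meta[s].role != "wildtype"]) >= 2:
            return "spontaneous", f"shared-in-group:{group}"
    carrier_groups = {meta[s].experiment_group for s in fixed}
    if len(carrier_groups) >= 2:
        return "spontaneous", "cross-group"
    for s in nonwt:
        if meta[s].lineage_wt in chimeric:
            return "spontaneous", "subclonal-in-wt"
    if any(meta[s].role == "control" for s in fixed):
        return "spontaneous", "control-carrier"
    # 6. confined to PEG-exposed plants
    if fixed and all(meta[s].role in PEG_EXPOSED_ROLES for s in fixed):
        return "treatment_associated", "peg-exposed-only"
    return "unattributed", "no-rule-matched"


def count_table(
    classified: Sequence[ClassifiedVariant],
    metadata: Sequence[SampleMeta],
    nuclease_kinds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-plant mutation counts relative to the matched wild type.

    Counts fixed SNVs and InDels in the mutation categories (everything
    except reference/lineage polymorphism) for each non-wild-type,
    non-excluded plant.  ``strategy`` is the plant's role, refined to the
    nuclease kind (``crispr``/``talen``) for edited plants when
    ``nuclease_kinds`` maps nuclease ids to kinds.
    """
    kinds = dict(nuclease_kinds or {})
    rows = []
    for m in metadata:
        if m.excluded or m.role == "wildtype":
            continue
        strategy = m.role
        if m.role == "edited":
            strategy = kinds.get(m.nuclease_id, "edited")
        n_snv = n_indel = 0
        for v in classified:
            if v.category in MUTATION_CATEGORIES and m.sample_id in v.carriers:
                if v.var_type == "SNV":
                    n_snv += 1
                else:
                    n_indel += 1
        rows.append(
            {
                "sample_id": m.sample_id,
                "experiment_group": m.experiment_group,
                "role": m.role,
                "strategy": strategy,
                "nuclease_id": m.nuclease_id or "",
                "n_snv": n_snv,
                "n_indel": n_indel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "experiment_group", "role", "strategy",
                 "nuclease_id", "n_snv", "n_indel"],
    )


def attribution_summary(classified: Sequence[ClassifiedVariant]) -> dict:
    """Category totals plus the joint 'not attributable' tally.

    The grand total equals the SNV total plus the InDel total, and the
    disjoint category counts sum to the number of classified sites.
    """
    totals = {c: 0 for c in CATEGORIES}
    n_snv = n_indel = 0
    for v in classified:
        totals[v.category] += 1
        if v.var_type == "SNV":
            n_snv += 1
        else:
            n_indel += 1
    return {
        "by_category": totals,
        "n_snv": n_snv,
        "n_indel": n_indel,
        "n_total": n_snv + n_indel,
        "not_attributable": totals["treatment_associated"] + totals["unattributed"],
    }
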