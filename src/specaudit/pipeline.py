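"""Hard filtering of haploid variant calls and the cross-sample site matrix.

Calls are retained iff QUAL > 20, total depth > 3 and >1 read supports the
alternate allele (all strict).  Because the organism is haploid and every
plant is a clone, an allele fraction >= 0.8 marks a fixed variant; lower
fractions down to a configurable floor are treated as chimeric (subclonal)
evidence, and anything below the floor as caller noise.  Only sites covered
in every non-excluded sample enter classification; the rest are kept in a
QC sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import SampleMeta, VariantCall

logger = logging.getLogger(__name__)

QUAL_MIN = 20.0
DEPTH_MIN = 3
ALT_DEPTH_MIN = 1
VAF_FIXED = 0.8
CHIMERA_FLOOR = 0.05
LARGE_INDEL_BP = 50

STATE_FIXED = "fixed_alt"
STATE_CHIMERIC = "chimeric_alt"
STATE_REF = "ref"
STATE_UNCOVERED = "uncovered"


def filter_calls(
    calls: Sequence[VariantCall],
    qual_min: float = QUAL_MIN,
    depth_min: int = DEPTH_MIN,
    alt_depth_min: int = ALT_DEPTH_MIN,
) -> list[VariantCall]:
    """Apply the hard quality/coverage filters (all thresholds strict)."""
    return [
        c
        for c in calls
        if c.qual > qual_min and c.depth > depth_min and c.alt_depth > alt_depth_min
    ]


def apply_vaf_rule(call: VariantCall, chimera_floor: float = CHIMERA_FLOOR) -> str:
    """Haploid allele-fraction rule.

    VAF >= 0.8 -> ``fixed_alt``; chimera_floor <= VAF < 0.8 ->
    ``chimeric_alt``; below the floor (or zero depth) -> ``rejected``.
    """
    if call.depth == 0:
        return "rejected"
    if call.vaf >= VAF_FIXED:
        return STATE_FIXED
    if call.vaf >= chimera_floor:
        return STATE_CHIMERIC
    return "rejected"


@dataclass
class VariantMatrix:
    """Presence/absence states over the union of sites x samples.

    ``sites``/``states``/``vafs``/``depths`` share a ``chrom:pos:ref>alt``
    string index and cover the classifiable sites (covered in every sample,
    with at least one fixed carrier).  ``dropped`` records the QC sidecar
    with a per-site reason.
    """

    samples: list[str]
    sites: pd.DataFrame
    states: pd.DataFrame
    vafs: pd.DataFrame
    depths: pd.DataFrame
    dropped: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sites)


def _site_id(key: tuple[str, int, str, str]) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


def build_site_matrix(
    calls: Sequence[VariantCall],
    metadata: Sequence[SampleMeta],
    depths: Mapping[tuple[str, int, str], int],
    chimera_floor: float = CHIMERA_FLOOR,
) -> VariantMatrix:
    """Assemble the all-samples state matrix over the union of call sites.

    ``depths`` supplies the per-(chrom, pos, sample) total depth at
    positions where a sample has no call (available from joint-called
    multi-sample VCFs); a sample without a call is ``ref`` if covered at
    depth > 3 there, else ``uncovered``.  Sites uncovered in any
    non-excluded sample, or with no fixed carrier, go to the QC sidecar.
    """
    sample_ids = [m.sample_id for m in metadata if not m.excluded]
    known = {m.sample_id for m in metadata}
    missing_depth_warned = False

    by_key: dict[tuple[str, int, str, str], dict[str, VariantCall]] = {}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call sample {c.sample_id!r} absent from metadata")
        if c.sample_id in sample_ids:
            by_key.setdefault(c.key, {})[c.sample_id] = c

    site_rows, state_rows, vaf_rows, depth_rows, dropped_rows = [], [], [], [], []
    for key in sorted(by_key):
        chrom, pos, ref, alt = key
        states: dict[str, str] = {}
        vafs: dict[str, float] = {}
        dps: dict[str, int] = {}
        for s in sample_ids:
            call = by_key[key].get(s)
            if call is not None:
                state = apply_vaf_rule(call, chimera_floor)
                if state == "rejected":
                    # treated as a false-positive call: sample is reference
                    state = STATE_REF if call.depth > DEPTH_MIN else STATE_UNCOVERED
                states[s] = state
                vafs[s] = call.vaf
                dps[s] = call.depth
            else:
                dp = depths.get((chrom, pos, s))
                if dp is None:
                    if not missing_depth_warned:
                        logger.warning(
                            "no depth information for uncalled samples (e.g. %s at "
                            "%s:%d); assuming reference", s, chrom, pos,
                        )
                        missing_depth_warned = True
                    states[s] = STATE_REF
                    vafs[s] = 0.0
                    dps[s] = -1
                    continue
                states[s] = STATE_REF if dp > DEPTH_MIN else STATE_UNCOVERED
                vafs[s] = 0.0
                dps[s] = dp

        sid = _site_id(key)
        var_type = "SNV" if len(ref) == 1 and len(alt) == 1 else "InDel"
        size_class = "large" if abs(len(ref) - len(alt)) > LARGE_INDEL_BP else "small"
        site = {
            "site_id": sid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "var_type": var_type, "size_class": size_class,
        }
        if any(st == STATE_UNCOVERED for st in states.values()):
            dropped_rows.append({**site, "reason": "uncovered_in_sample"})
        elif not any(st == STATE_FIXED for st in states.values()):
            dropped_rows.append({**site, "reason": "no_fixed_carrier"})
        else:
            site_rows.append(site)
            state_rows.append({"site_id": sid, **states})
            vaf_rows.append({"site_id": sid, **vafs})
            depth_rows.append({"site_id": sid, **dps})

    def _frame(rows: list[dict], columns: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=["site_id"] + columns)
        return df.set_index("site_id")

    site_cols = ["chrom", "pos", "ref", "alt", "var_type", "size_class"]
    return VariantMatrix(
        samples=sample_ids,
        sites=_frame(site_rows, site_cols),
        states=_frame(state_rows, sample_ids),
        vafs=_frame(vaf_rows, sample_ids),
        depths=_frame(depth_rows, sample_ids),
        dropped=pd.DataFrame(
            dropped_rows, columns=["site_id"] + site_cols + ["reason"]
        ),
    )
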