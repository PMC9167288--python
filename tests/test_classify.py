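"""The attribution decision tree on hand-built matrices."""

from __future__ import annotations

import pytest

from specaudit import (
    SampleMeta,
    VariantCall,
    build_site_matrix,
    classify_variants,
    count_table,
    attribution_summary,
)
from specaudit.offtargets import OffTargetSite
from specaudit.study_design import study_metadata

META = study_metadata()
ACTIVE = [m for m in META if not m.excluded]
IDS = [m.sample_id for m in ACTIVE]

WINDOWS = {
    "sgRNA1": ("chr1", 950, 1100),
    "sgRNA2": ("chr1", 1950, 2100),
    "talen1": ("chr1", 2950, 3150),
}


def _matrix(carrier_map, chimeric=(), pos=5000, ref="A", alt="T"):
    """Matrix with one site; carriers fixed, ``chimeric`` subclonal."""
    calls = []
    for s in carrier_map:
        calls.append(VariantCall("chr1", pos, ref, alt, 60.0, 20, 20, s))
    for s in chimeric:
        calls.append(VariantCall("chr1", pos, ref, alt, 60.0, 20, 8, s))
    depths = {("chr1", pos, s): 30 for s in IDS}
    return build_site_matrix(calls, META, depths)


def _classify(carriers, chimeric=(), pos=5000, sites=()):
    m = _matrix(carriers, chimeric, pos=pos)
    out = classify_variants(m, META, WINDOWS, sites)
    assert len(out) == 1
    return out[0]


def test_fixed_in_all_samples_is_reference_polymorphism():
    v = _classify(IDS)
    assert v.category == "ref_polymorphism"


def test_fixed_throughout_one_pedigree_is_lineage_polymorphism():
    group_a = [s for s in IDS if s.startswith(("WT_A", "CRIS"))]
    v = _classify(group_a)
    assert v.category == "lineage_polymorphism"
    assert v.evidence == "lineage:A"


def test_deletion_inside_guide_window_is_on_target():
    v = _classify(["CRIS1#1"], pos=1001)
    assert v.category == "on_target"
    assert v.evidence == "on-target:sgRNA1"


def test_on_target_window_is_per_nuclease():
    # CRIS1#1 carrying a variant in the sgRNA2 window is NOT on-target
    v = _classify(["CRIS1#1"], pos=2001)
    assert v.category == "treatment_associated"


def test_predicted_offtarget_hit_requires_matching_nuclease():
    site = OffTargetSite("chr1", 7000, 7023, "+", 3, "sgRNA1")
    v = _classify(["CRIS1#1"], pos=7010, sites=[site])
    assert v.category == "predicted_off_target_hit"
    v = _classify(["CRIS2#1"], pos=7010, sites=[site])
    assert v.category == "treatment_associated"


def test_peg_only_variant_is_treatment_associated():
    v = _classify(["PEG#1"])
    assert v.category == "treatment_associated"


def test_chimeric_echo_in_wildtype_makes_it_spontaneous():
    # same carrier as above, but subclonally present in the matched WT
    v = _classify(["PEG#1"], chimeric=["WT_C"])
    assert v.category == "spontaneous"
    assert v.evidence == "subclonal-in-wt"


def test_sharing_between_siblings_is_spontaneous():
    v = _classify(["PEG#1", "Control#1"])
    assert v.category == "spontaneous"
    assert v.evidence == "shared-in-group:C"


def test_control_carrier_is_spontaneous():
    v = _classify(["Control#2"])
    assert v.category == "spontaneous"


def test_cross_group_sharing_is_flagged_spontaneous():
    v = _classify(["CRIS1#1", "TAL#1"])
    assert v.category == "spontaneous"
    assert v.evidence == "cross-group"


def test_wildtype_only_variant_is_unattributed():
    v = _classify(["WT_C"])
    assert v.category == "unattributed"


def test_classification_is_invariant_to_sample_order():
    m1 = _matrix(["PEG#1", "Control#1"])
    shuffled = list(reversed(META))
    calls = [VariantCall("chr1", 5000, "A", "T", 60.0, 20, 20, s)
             for s in ["Control#1", "PEG#1"]]
    depths = {("chr1", 5000, s): 30 for s in IDS}
    m2 = build_site_matrix(calls, shuffled, depths)
    v1 = classify_variants(m1, META, WINDOWS)[0]
    v2 = classify_variants(m2, shuffled, WINDOWS)[0]
    assert (v1.category, set(v1.carriers)) == (v2.category, set(v2.carriers))


def test_removing_edited_plants_never_creates_nuclease_categories():
    no_edit_meta = [m for m in META if m.role != "edited"]
    ids = [m.sample_id for m in no_edit_meta if not m.excluded]
    calls = [VariantCall("chr1", 1001, "A", "T", 60.0, 20, 20, "PEG#1")]
    depths = {("chr1", 1001, s): 30 for s in ids}
    m = build_site_matrix(calls, no_edit_meta, depths)
    out = classify_variants(m, no_edit_meta, WINDOWS)
    assert out[0].category not in {"on_target", "predicted_off_target_hit"}


# ---------------------------------------------------------------------------
# counting and summaries
# ---------------------------------------------------------------------------


def _multi_site_matrix():
    """Two ref polymorphisms, one spontaneous (control), one PEG SNV,
    one PEG InDel."""
    depths = {}
    calls = []

    def add(pos, carriers, ref="A", alt="T"):
        for s in carriers:
            calls.append(VariantCall("chr1", pos, ref, alt, 60.0, 20, 20, s))
        for s in IDS:
            depths[("chr1", pos, s)] = 30

    add(100, IDS)
    add(200, IDS)
    add(300, ["Control#1"])
    add(400, ["PEG#1"])
    add(500, ["PEG#1"], ref="ATT", alt="A")
    return build_site_matrix(calls, META, depths)


def test_count_table_and_summary_on_toy_matrix():
    m = _multi_site_matrix()
    classified = classify_variants(m, META, WINDOWS)
    summary = attribution_summary(classified)
    assert summary["by_category"]["ref_polymorphism"] == 2
    assert summary["by_category"]["spontaneous"] == 1
    assert summary["by_category"]["treatment_associated"] == 2
    assert summary["n_total"] == 5 == sum(summary["by_category"].values())
    assert summary["n_snv"] + summary["n_indel"] == summary["n_total"]

    counts = count_table(classified, META,
                         {"sgRNA1": "crispr", "sgRNA2": "crispr", "talen1": "talen"})
    by = counts.set_index("sample_id")
    # polymorphisms never enter per-plant counts
    assert by.loc["CRIS1#1", ["n_snv", "n_indel"]].tolist() == [0, 0]
    assert by.loc["Control#1", "n_snv"] == 1
    assert by.loc["PEG#1", ["n_snv", "n_indel"]].tolist() == [1, 1]
    assert "WT_C" not in by.index and "PEG-DNA#2" not in by.index
    assert set(by.strategy) == {"crispr", "talen", "control", "peg", "peg_dna"}


def test_edited_plant_without_nuclease_is_an_error():
    bad_meta = [
        SampleMeta("WT", "A", "WT", "wildtype"),
        SampleMeta("E1", "A", "WT", "edited", nuclease_id="g1"),
    ]
    object.__setattr__(bad_meta[1], "nuclease_id", None)  # bypass constructor
    calls = [VariantCall("chr1", 10, "A", "T", 60.0, 20, 20, "E1")]
    depths = {("chr1", 10, s): 30 for s in ("WT", "E1")}
    m = build_site_matrix(calls, bad_meta, depths)
    with pytest.raises(ValueError, match="nuclease"):
        classify_variants(m, bad_meta, WINDOWS)
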