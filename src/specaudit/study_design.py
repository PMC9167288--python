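"""Published numbers from the P. patens editing-specificity experiment.

The study this package re-implements edited the haploid moss
*Physcomitrium patens* at the *APT* locus with either CRISPR-Cas9 (two
guides) or a TALEN pair, sequenced the edited plants together with their
clonal wild-type parents and a PEG-transfection control series, and
attributed every whole-genome variant to polymorphism, spontaneous
mutation, treatment or nuclease activity.  The printed per-plant counts,
clone tallies and classification totals below are inputs to the
worked-example arithmetic (per-strategy means, efficiency percentages,
bookkeeping totals); they are not desk-reproducible from reads and are
kept here as the published reference values.
"""

from __future__ import annotations

import pandas as pd

from .io import SampleMeta

#: per-plant SNV/InDel counts relative to the matched wild type
PLANT_COUNTS = pd.DataFrame(
    [
        ("Control#1", "C", "control", "control", 0, 0),
        ("Control#2", "C", "control", "control", 0, 3),
        ("PEG#1", "C", "peg", "peg", 20, 19),
        ("PEG#2", "C", "peg", "peg", 10, 19),
        ("PEG-DNA#1", "C", "peg_dna", "peg_dna", 16, 24),
        ("CRIS1#1", "A", "edited", "crispr", 9, 16),
        ("CRIS1#2", "A", "edited", "crispr", 11, 20),
        ("CRIS2#1", "A", "edited", "crispr", 6, 29),
        ("CRIS2#2", "A", "edited", "crispr", 7, 13),
        ("TAL#1", "B", "edited", "talen", 21, 31),
        ("TAL#2", "B", "edited", "talen", 11, 33),
    ],
    columns=["sample_id", "experiment_group", "role", "strategy", "n_snv", "n_indel"],
)

#: editing-efficiency table: strategy, regenerant clones, 2-FA-resistant
#: clones, and the printed efficiency (%; sgRNA values are means of three
#: experiments, so the pooled ratio can differ in the last decimal)
EFFICIENCY = pd.DataFrame(
    [
        ("crispr_sgRNA1", 71_100, 1_718, 2.41),
        ("crispr_sgRNA2", 61_600, 2_077, 3.39),
        ("talen", 68_300, 56, 0.08),
    ],
    columns=["strategy", "regenerants", "resistant", "printed_efficiency_pct"],
)

#: genome-wide classification totals
TOTAL_SNV = 5_184
TOTAL_INDEL = 4_182
SHARED_WITH_REFERENCE = (4_487, 2_994)  # SNVs, InDels common to all plants
WT_PRIVATE = (586, 967)  # SNVs, InDels private to individual wild types
NOT_ATTRIBUTABLE = 318

#: homology-predicted candidate off-target counts (<=5 mismatches)
PREDICTED_OFFTARGETS = {"crispr_sgRNA1": 9, "crispr_sgRNA2": 4, "talen": 0}


def reported_totals() -> dict:
    """Bookkeeping of the published variant totals."""
    return {
        "n_snv": TOTAL_SNV,
        "n_indel": TOTAL_INDEL,
        "n_total": TOTAL_SNV + TOTAL_INDEL,
        "not_attributable": NOT_ATTRIBUTABLE,
    }


def study_metadata() -> list[SampleMeta]:
    """The sequenced sample design: three wild-type pedigrees, their
    edited/control/PEG derivatives, and the contaminated PEG-DNA#2 sample
    flagged as excluded."""
    rows = [
        SampleMeta("WT_A", "A", "WT_A", "wildtype"),
        SampleMeta("CRIS1#1", "A", "WT_A", "edited", nuclease_id="sgRNA1"),
        SampleMeta("CRIS1#2", "A", "WT_A", "edited", nuclease_id="sgRNA1"),
        SampleMeta("CRIS2#1", "A", "WT_A", "edited", nuclease_id="sgRNA2"),
        SampleMeta("CRIS2#2", "A", "WT_A", "edited", nuclease_id="sgRNA2"),
        SampleMeta("WT_B", "B", "WT_B", "wildtype"),
        SampleMeta("TAL#1", "B", "WT_B", "edited", nuclease_id="talen1"),
        SampleMeta("TAL#2", "B", "WT_B", "edited", nuclease_id="talen1"),
        SampleMeta("WT_C", "C", "WT_C", "wildtype"),
        SampleMeta("Control#1", "C", "WT_C", "control"),
        SampleMeta("Control#2", "C", "WT_C", "control"),
        SampleMeta("PEG#1", "C", "WT_C", "peg"),
        SampleMeta("PEG#2", "C", "WT_C", "peg"),
        SampleMeta("PEG-DNA#1", "C", "WT_C", "peg_dna"),
        SampleMeta("PEG-DNA#2", "C", "WT_C", "peg_dna", excluded=True),
    ]
    return rows
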