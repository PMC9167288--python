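"""Readers and writers for the standard formats the pipeline touches.

FASTA genomes (Biopython), multi-sample VCF v4.2 with GT:DP:AD genotypes
(pysam), BED6 site tables, and the tab-separated sample-metadata design
table describing experiment groups, lineage wild types and treatments.

Internal coordinates are 0-based half-open; VCF positions are converted at
the boundary (``VariantCall.pos`` stays 1-based, as in the file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ROLES = {"wildtype", "control", "peg", "peg_dna", "edited"}
#: roles whose protoplasts went through PEG-mediated transfection
PEG_EXPOSED_ROLES = {"peg", "peg_dna", "edited"}

METADATA_COLUMNS = [
    "sample_id",
    "experiment_group",
    "lineage_wt",
    "role",
    "nuclease_id",
    "excluded",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome of uppercase DNA over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if not self.seq:
            raise ValueError(f"chromosome {self.name!r} has empty sequence")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def genome_dict(genome: Iterable[GenomeSequence] | Mapping[str, str]) -> dict[str, str]:
    """Normalise a genome (list of records or mapping) to ``{name: seq}``."""
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.name: g.seq for g in genome}


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced plant: its experiment group, matched wild type and role.

    ``lineage_wt`` names the wild-type plant the sample was clonally
    regenerated from (wild types point at themselves).  ``nuclease_id``
    links edited plants to the nuclease they were transfected with.
    """

    sample_id: str
    experiment_group: str
    lineage_wt: str
    role: str
    nuclease_id: str | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.role == "edited" and not self.nuclease_id:
            raise ValueError(f"edited sample {self.sample_id} has no nuclease_id")


@dataclass(frozen=True)
class VariantCall:
    """One sample's alternate-allele call at a site (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_depth: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} > depth {self.depth} at "
                f"{self.chrom}:{self.pos} ({self.sample_id})"
            )

    @property
    def vaf(self) -> float:
        return 0.0 if self.depth == 0 else self.alt_depth / self.depth

    @property
    def var_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def size_class(self) -> str:
        """``large`` iff the length change exceeds 50 bp, else ``small``."""
        return "large" if abs(len(self.ref) - len(self.alt)) > 50 else "small"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleGenotype:
    """Per-sample fields of one biallelic VCF record (haploid GT)."""

    gt: int  # 0 = ref, 1 = alt
    dp: int
    ad_ref: int
    ad_alt: int


@dataclass
class VcfRecord:
    """One biallelic multi-sample VCF row held in memory."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: dict[str, SampleGenotype] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (wrapped or single-line) FASTA file into genome records.

    Sequences are uppercased; record order is preserved.  Duplicate names
    and empty records are errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seen.add(name)
        records.append(GenomeSequence(name, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(genome: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.name, description="") for g in genome]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim a ref/alt pair (shared suffix then prefix), keeping
    at least one base of each and adjusting the 1-based position."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _vcf_header(samples: Sequence[str], contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VcfRecord],
    samples: Sequence[str],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write biallelic multi-sample records as an uncompressed VCF v4.2."""
    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt))
            rec.qual = r.qual
            for s in samples:
                g = r.genotypes[s]
                rec.samples[s]["GT"] = (g.gt,)
                rec.samples[s]["DP"] = g.dp
                rec.samples[s]["AD"] = (g.ad_ref, g.ad_alt)
            vf.write(rec)


def read_vcf_records(path: str | Path) -> tuple[list[VcfRecord], list[str]]:
    """Read a multi-sample VCF into biallelic in-memory records.

    Multiallelic rows are split into one record per alternate allele; a
    sample carries allele *k* iff its GT contains *k*.  Returns the records
    and the header sample order.
    """
    records: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for row in vf:
            alts = row.alts or ()
            for k, alt in enumerate(alts, start=1):
                genos: dict[str, SampleGenotype] = {}
                skip = False
                for s in samples:
                    sd = row.samples[s]
                    gt = sd.get("GT")
                    dp = sd.get("DP")
                    ad = sd.get("AD")
                    if dp is None or ad is None or len(ad) <= k or ad[k] is None:
                        logger.warning(
                            "skipping %s:%s alt %s: sample %s missing DP/AD",
                            row.chrom, row.pos, alt, s,
                        )
                        skip = True
                        break
                    carries = gt is not None and k in gt
                    genos[s] = SampleGenotype(
                        gt=1 if carries else 0,
                        dp=int(dp),
                        ad_ref=int(ad[0] or 0),
                        ad_alt=int(ad[k]),
                    )
                if skip:
                    continue
                qual = float(row.qual) if row.qual is not None else 0.0
                records.append(
                    VcfRecord(row.chrom, row.pos, row.ref, str(alt), qual, genos)
                )
    return records, samples


def read_vcf(path: str | Path, sample_ids: Sequence[str] | None = None) -> list[VariantCall]:
    """Extract per-sample alternate calls (non-reference GT) from a VCF.

    Alleles are parsimony-trimmed so cross-sample site matching is
    well-defined.  ``sample_ids`` restricts output to those samples.
    """
    records, header_samples = read_vcf_records(path)
    return calls_from_records(records, sample_ids or header_samples)


def calls_from_records(
    records: Sequence[VcfRecord], sample_ids: Sequence[str]
) -> list[VariantCall]:
    """Per-sample alternate calls from in-memory records (see read_vcf)."""
    wanted = set(sample_ids)
    calls: list[VariantCall] = []
    for rec in records:
        pos, ref, alt = trim_alleles(rec.pos, rec.ref, rec.alt)
        for s, g in rec.genotypes.items():
            if s in wanted and g.gt == 1:
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        qual=rec.qual,
                        depth=g.dp,
                        alt_depth=min(g.ad_alt, g.dp),
                        sample_id=s,
                    )
                )
    return calls


def site_depths_from_records(
    records: Sequence[VcfRecord],
) -> dict[tuple[str, int, str], int]:
    """Per-(chrom, pos, sample) total depth from joint-called records."""
    depths: dict[tuple[str, int, str], int] = {}
    for rec in records:
        for s, g in rec.genotypes.items():
            depths[(rec.chrom, rec.pos, s)] = g.dp
    return depths


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(sites: Iterable, path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open); score column = mismatches."""
    with open(path, "w") as fh:
        for s in sites:
            if s.end <= s.start:
                raise ValueError(f"invalid interval {s.chrom}:{s.start}-{s.end}")
            name = getattr(s, "nuclease_id", None) or "site"
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.mismatches}\t{s.strand}\n"
            )


def read_bed(path: str | Path) -> list["OffTargetSite"]:
    from .offtargets import OffTargetSite  # local import avoids a cycle

    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            sites.append(
                OffTargetSite(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    mismatches=int(score),
                    nuclease_id=name,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def validate_metadata(samples: Sequence[SampleMeta]) -> None:
    """Enforce the design-table invariants.

    Exactly one wild type per experiment group; every sample's
    ``lineage_wt`` must name that group's wild type; wild types reference
    themselves.  Excluded samples still belong to their group.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    by_group: dict[str, list[SampleMeta]] = {}
    for s in samples:
        by_group.setdefault(s.experiment_group, []).append(s)
    for group, members in by_group.items():
        wts = [m for m in members if m.role == "wildtype"]
        if len(wts) != 1:
            raise ValueError(
                f"experiment group {group!r} has {len(wts)} wild types (need exactly 1)"
            )
        wt = wts[0]
        if wt.lineage_wt != wt.sample_id:
            raise ValueError(f"wild type {wt.sample_id} must reference itself")
        for m in members:
            if m.lineage_wt != wt.sample_id:
                raise ValueError(
                    f"sample {m.sample_id}: lineage_wt {m.lineage_wt!r} is not the "
                    f"wild type of group {group!r}"
                )


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        nid = row.get("nuclease_id", "") or None
        excluded = str(row.get("excluded", "")).strip().lower() in {"1", "true", "yes"}
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                experiment_group=row["experiment_group"],
                lineage_wt=row["lineage_wt"],
                role=row["role"],
                nuclease_id=nid,
                excluded=excluded,
            )
        )
    validate_metadata(samples)
    return samples


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "experiment_group": s.experiment_group,
                "lineage_wt": s.lineage_wt,
                "role": s.role,
                "nuclease_id": s.nuclease_id or "",
                "excluded": "true" if s.excluded else "false",
            }
            for s in samples
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
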