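"""Truth-labelled synthetic editing experiments.

Emulates the study design the pipeline audits: three diverged clonal
wild-type lineages sharing ancestral polymorphisms against the reference
assembly, clonally regenerated plants per lineage (untreated controls,
PEG-treated, PEG+DNA, and nuclease-edited plants), per-plant spontaneous
mutations (optionally echoed subclonally in the wild type or shared with a
sibling regenerant), PEG-treatment-induced SNVs/InDels placed
length-proportionally across chromosomes, on-target edits drawn from a
microhomology-deletion (Alt-EJ) repair model, optional planted off-target
edits, and negative-binomial depth with binomial allele-depth noise.

Every emitted alternate call carries exactly one truth label, so the
downstream filtering/classification stages can be scored against ground
truth without any external data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    GenomeSequence,
    SampleGenotype,
    SampleMeta,
    VcfRecord,
    genome_dict,
    write_fasta,
    write_metadata,
    write_vcf,
)
from .offtargets import NucleaseSpec, revcomp
from .repair import max_microhomology

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "category", "true_af"]

TRUE_QUAL = 60.0
_BASES = np.array(list("ACGT"))

# edit modes for simulate_on_target_edit
ALT_EJ_MODE = "alt_ej"
ALT_EJ_SUB_MODE = "alt_ej_substitution"
C_NHEJ_MODE = "c_nhej"


@dataclass(frozen=True)
class PlantedOffTarget:
    """A degenerate copy of a nuclease query planted into the genome.

    If ``edited_sample`` is set, that plant additionally carries a small
    deletion at the copy (a true off-target mutation for recovery tests).
    """

    nuclease_id: str
    chrom: str
    pos: int  # 0-based start of the planted copy
    n_mismatches: int = 2
    edited_sample: str | None = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Counts and rates are desk-scale stand-ins for the study design:
    treatment-induced means follow the observed PEG-plant counts, the
    spontaneous rate matches the near-zero counts seen in untreated
    controls, and sequencing depth is drawn around the middle of the
    reported 14-39x range with negative-binomial overdispersion.
    """

    chrom_lengths: tuple[int, ...] = (150_000, 100_000, 60_000)
    n_ref_polymorphisms: int = 300
    n_lineage_polymorphisms: int = 60
    spontaneous_rate: float = 1.0
    chimeric_rate: float = 0.5
    chimeric_echo_prob: float = 0.3
    share_prob: float = 0.15
    peg_snv_mean: float = 15.0
    peg_indel_mean: float = 19.0
    indel_fraction: float = 0.45
    c_nhej_prob: float = 0.25
    mean_depth: float = 25.0
    depth_dispersion: float = 8.0
    noise_rate: float = 10.0
    seed: int = 0
    nuclease_specs: tuple[NucleaseSpec, ...] = ()
    planted_offtargets: tuple[PlantedOffTarget, ...] = ()

    def __post_init__(self) -> None:
        if any(l < 1000 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must all be >= 1000")
        for name in ("n_ref_polymorphisms", "n_lineage_polymorphisms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("spontaneous_rate", "chimeric_rate", "peg_snv_mean",
                     "peg_indel_mean", "noise_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)


def load_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = tuple(
        NucleaseSpec(**s) for s in raw.pop("nuclease_specs", [])
    )
    planted = tuple(
        PlantedOffTarget(**p) for p in raw.pop("planted_offtargets", [])
    )
    if "chrom_lengths" in raw:
        raw["chrom_lengths"] = tuple(raw["chrom_lengths"])
    return SimulationConfig(nuclease_specs=specs, planted_offtargets=planted, **raw)


def _rng(seed: int, *tags) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, tags) so adding a sample
    does not perturb the draws of the others."""
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> list[GenomeSequence]:
    """I.i.d. uniform A/C/G/T chromosomes of the configured lengths."""
    rng = _rng(config.seed, "genome")
    out = []
    for i, length in enumerate(config.chrom_lengths, start=1):
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        out.append(GenomeSequence(f"chr{i}", seq))
    return out


def plant_target_locus(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
    chrom: str,
    pos: int,
    talen_spacer: int = 16,
) -> list[GenomeSequence]:
    """Write a nuclease's exact target into the genome at ``pos``.

    For CRISPR the protospacer+PAM is inserted with the cut site 3 bp
    upstream of the PAM; for TALEN the left half-site, a spacer and the
    reverse complement of the right half-site are inserted with the cut in
    the middle of the spacer.  In both cases a 3-bp microhomology pair is
    embedded flanking the expected cut so Alt-EJ deletion outcomes exist.
    ``spec.on_target`` and ``spec.cut_site`` are filled in.
    """
    gdict = genome_dict(genome)
    seq = list(gdict[chrom])
    if spec.kind == "crispr":
        cassette = spec.query
        if pos < 50 or pos + len(cassette) + 50 > len(seq):
            raise ValueError("target locus too close to a chromosome end")
        seq[pos:pos + len(cassette)] = cassette
        cut = pos + len(spec.protospacer) - 3
        # echo protospacer bases [cut-8, cut-5) just downstream of the PAM:
        # deleting [cut-5, cut+10) then collapses a 3-bp microhomology
        seq[cut + 7:cut + 10] = seq[cut - 8:cut - 5]
        span = (chrom, pos, pos + len(cassette))
    else:
        left, right = spec.left_site, revcomp(spec.right_site)
        total = len(left) + talen_spacer + len(right)
        if talen_spacer < 12 or not (spec.spacer_min <= talen_spacer <= spec.spacer_max):
            raise ValueError("talen_spacer must be >= 12 and within the spacer range")
        if pos < 50 or pos + total + 50 > len(seq):
            raise ValueError("target locus too close to a chromosome end")
        seq[pos:pos + len(left)] = left
        seq[pos + len(left) + talen_spacer:pos + total] = right
        cut = pos + len(left) + talen_spacer // 2
        seq[cut + 4:cut + 7] = seq[cut - 6:cut - 3]
        span = (chrom, pos, pos + total)
    spec.on_target = span
    spec.cut_site = (chrom, cut)
    gdict[chrom] = "".join(seq)
    return [GenomeSequence(n, s) for n, s in gdict.items()]


def plant_offtarget_copy(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
    chrom: str,
    pos: int,
    n_mismatches: int,
    rng: np.random.Generator,
) -> list[GenomeSequence]:
    """Plant a copy of the nuclease query carrying ``n_mismatches`` random
    substitutions (a homology-predictable candidate off-target)."""
    query = spec.query if spec.kind == "crispr" else spec.left_site
    gdict = genome_dict(genome)
    seq = list(gdict[chrom])
    if pos < 50 or pos + len(query) + 50 > len(seq):
        raise ValueError("off-target copy too close to a chromosome end")
    copy = list(query)
    sites = rng.choice(len(copy), size=n_mismatches, replace=False)
    for i in sites:
        copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
    seq[pos:pos + len(copy)] = copy
    gdict[chrom] = "".join(seq)
    return [GenomeSequence(n, s) for n, s in gdict.items()]


def simulate_reference(config: SimulationConfig) -> list[GenomeSequence]:
    """Genome with all nuclease target loci (and planted off-target
    copies) written in; mutates the specs' on_target/cut_site fields."""
    genome = simulate_genome(config)
    longest = max(genome, key=len).name
    base = max(len(genome_dict(genome)[longest]) // 4, 1000)
    for i, spec in enumerate(config.nuclease_specs):
        genome = plant_target_locus(genome, spec, longest, base + i * 500)
    rng = _rng(config.seed, "offtarget-copies")
    for p in config.planted_offtargets:
        spec = _spec_by_id(config, p.nuclease_id)
        genome = plant_offtarget_copy(genome, spec, p.chrom, p.pos,
                                      p.n_mismatches, rng)
    return genome


def _spec_by_id(config: SimulationConfig, nuclease_id: str) -> NucleaseSpec:
    for spec in config.nuclease_specs:
        if spec.nuclease_id == nuclease_id:
            return spec
    raise ValueError(f"unknown nuclease_id {nuclease_id!r}")


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------


def default_design(config: SimulationConfig) -> list[SampleMeta]:
    """The study's sampling design, adapted to the configured nucleases.

    With CRISPR guides: a wild type plus two edited plants per guide
    (group A).  With a TALEN pair: a wild type plus two edited plants
    (group B).  Always: a wild type with two untreated controls, two
    PEG-treated and one PEG+DNA plant (group C).
    """
    samples: list[SampleMeta] = []
    crispr = [s for s in config.nuclease_specs if s.kind == "crispr"]
    talen = [s for s in config.nuclease_specs if s.kind == "talen"]
    if crispr:
        samples.append(SampleMeta("WT_A", "A", "WT_A", "wildtype"))
        for i, spec in enumerate(crispr, start=1):
            for j in (1, 2):
                samples.append(
                    SampleMeta(f"CRIS{i}#{j}", "A", "WT_A", "edited",
                               nuclease_id=spec.nuclease_id)
                )
    if talen:
        samples.append(SampleMeta("WT_B", "B", "WT_B", "wildtype"))
        for j in (1, 2):
            samples.append(
                SampleMeta(f"TAL#{j}", "B", "WT_B", "edited",
                           nuclease_id=talen[0].nuclease_id)
            )
    samples.append(SampleMeta("WT_C", "C", "WT_C", "wildtype"))
    for j in (1, 2):
        samples.append(SampleMeta(f"Control#{j}", "C", "WT_C", "control"))
    for j in (1, 2):
        samples.append(SampleMeta(f"PEG#{j}", "C", "WT_C", "peg"))
    samples.append(SampleMeta("PEG-DNA#1", "C", "WT_C", "peg_dna"))
    return samples


def study_scale_config(seed: int = 7, with_planted_offtarget: bool = True) -> SimulationConfig:
    """Default full-scale study conditions: two CRISPR guides, one TALEN
    pair and the 14-sample three-pedigree design.

    The nuclease sequences are synthetic stand-ins with the geometry of
    the real reagents (20-nt protospacer + NGG PAM; 17-nt TALEN
    half-sites).  ``with_planted_offtarget`` additionally plants one
    2-mismatch copy of the first guide's target carrying a true edit in
    CRIS1#1, so off-target recovery can be scored.
    """
    specs = (
        NucleaseSpec("sgRNA1", "crispr",
                     protospacer="GACGTTACCGGATTGCCATG", pam="TGG"),
        NucleaseSpec("sgRNA2", "crispr",
                     protospacer="TTCAGGCTAAGCGTATACCA", pam="AGG"),
        NucleaseSpec("talen1", "talen",
                     left_site="TCCTGAGGACAAGTCAC", right_site="TGGACCTTAGACAAGTA"),
    )
    planted = (
        (PlantedOffTarget("sgRNA1", "chr2", 30_000, 2, "CRIS1#1"),)
        if with_planted_offtarget
        else ()
    )
    return SimulationConfig(seed=seed, nuclease_specs=specs,
                            planted_offtargets=planted)


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


class _SiteSpace:
    """Draws non-overlapping variant sites, chromosome-weighted by length."""

    _MARGIN = 120  # keep events away from chromosome ends
    _SPACING = 12  # min gap between events so alleles never overlap

    def __init__(self, genome: Sequence[GenomeSequence],
                 reserved: Iterable[tuple[str, int, int]] = ()):
        self.names = [g.name for g in genome]
        self.seqs = {g.name: g.seq for g in genome}
        lengths = np.array([len(g.seq) for g in genome], dtype=float)
        self.weights = lengths / lengths.sum()
        self.blocked: set[tuple[str, int]] = set()
        for chrom, start, end in reserved:
            self._block(chrom, start, end)

    def _block(self, chrom: str, start: int, end: int) -> None:
        for p in range(start - self._SPACING, end + self._SPACING):
            self.blocked.add((chrom, p))

    def draw(self, rng: np.random.Generator, want_indel: bool) -> tuple[str, int, str, str]:
        """One fresh site as (chrom, 1-based pos, ref, alt)."""
        for _ in range(2000):
            chrom = self.names[rng.choice(len(self.names), p=self.weights)]
            seq = self.seqs[chrom]
            pos0 = int(rng.integers(self._MARGIN, len(seq) - self._MARGIN))
            if (chrom, pos0) in self.blocked:
                continue
            if want_indel:
                size = int(min(rng.geometric(0.35), 12))
                if rng.random() < 0.5:  # deletion
                    ref = seq[pos0:pos0 + 1 + size]
                    alt = seq[pos0]
                else:  # insertion
                    ref = seq[pos0]
                    alt = ref + "".join(_BASES[rng.integers(0, 4, size=size)])
                span = (pos0, pos0 + len(ref))
            else:
                ref = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                span = (pos0, pos0 + 1)
            if any((chrom, p) in self.blocked for p in range(*span)):
                continue
            self._block(chrom, *span)
            return chrom, pos0 + 1, ref, alt
        raise ValueError("could not place variant: requested count exceeds "
                         "available positions")

    def register(self, chrom: str, start: int, end: int) -> None:
        self._block(chrom, start, end)


# ---------------------------------------------------------------------------
# on-target edits
# ---------------------------------------------------------------------------


def _find_mh_deletion(seq: str, cut: int, window: int = 12,
                      min_mh: int = 2) -> tuple[int, int, int]:
    """Best microhomology-collapsing deletion spanning the cut site.

    Returns (start, end, mh) of the deletion maximising junction
    microhomology (smallest span, then leftmost, on ties) among spans of
    length 3..2*window covering the cut within +/- ``window`` bp.
    """
    best = None
    for s in range(max(1, cut - window), cut + 1):
        for e in range(max(s + 3, cut), min(len(seq) - 1, cut + window) + 1):
            mh = max_microhomology(seq, (s, e))
            if mh < min_mh:
                continue
            rank = (-mh, e - s, s)
            if best is None or rank < best[0]:
                best = (rank, s, e, mh)
    if best is None:
        raise ValueError(f"no microhomology >= {min_mh} bp within {window} bp "
                         f"of the cut site")
    return best[1], best[2], best[3]


def simulate_on_target_edit(
    genome: Iterable[GenomeSequence] | Mapping[str, str],
    spec: NucleaseSpec,
    mode: str,
    rng: np.random.Generator | None = None,
) -> tuple[str, int, str, str]:
    """Draw one on-target repair outcome as (chrom, 1-based pos, ref, alt).

    ``alt_ej``: a deletion collapsing a flanking microhomology pair near
    the cut (junction microhomology >= 2 bp).  ``alt_ej_substitution``:
    the same deletion with one extra junction base substitution.
    ``c_nhej``: a 1-3 bp insertion or microhomology-free deletion at the
    cut.
    """
    if spec.cut_site is None:
        raise ValueError(f"nuclease {spec.nuclease_id} has no cut_site")
    rng = rng if rng is not None else np.random.default_rng(0)
    chrom, cut = spec.cut_site
    seq = genome_dict(genome)[chrom]
    if mode in (ALT_EJ_MODE, ALT_EJ_SUB_MODE):
        s, e, _mh = _find_mh_deletion(seq, cut)
        if mode == ALT_EJ_MODE:
            return chrom, s, seq[s - 1:e], seq[s - 1]
        # one junction substitution: mutate the base right after the
        # deleted block, avoiding the upstream flank base so the deletion
        # placement stays unambiguous
        forbidden = {seq[e], seq[s]}
        sub = str(rng.choice([b for b in "ACGT" if b not in forbidden]))
        return chrom, s, seq[s - 1:e + 1], seq[s - 1] + sub
    if mode == C_NHEJ_MODE:
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            ins = "".join(_BASES[rng.integers(0, 4, size=size)])
            return chrom, cut, seq[cut - 1], seq[cut - 1] + ins
        # microhomology-free deletion: shrink until the junction is clean
        for e in range(cut + size, cut, -1):
            if max_microhomology(seq, (cut, e)) < 2:
                return chrom, cut, seq[cut - 1:e], seq[cut - 1]
        ins = str(rng.choice(list("ACGT")))
        return chrom, cut, seq[cut - 1], seq[cut - 1] + ins
    raise ValueError(f"unknown edit mode {mode!r}")


# ---------------------------------------------------------------------------
# the experiment itself
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    genome: list[GenomeSequence]
    samples: list[SampleMeta]
    records: list[VcfRecord]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, experiment.vcf, metadata.tsv and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "vcf": outdir / "experiment.vcf",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        contigs = {g.name: len(g.seq) for g in self.genome}
        sample_ids = [s.sample_id for s in self.samples if not s.excluded]
        write_vcf(self.records, sample_ids, contigs, paths["vcf"])
        write_metadata(self.samples, paths["metadata"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


class _EventTable:
    """Accumulates (site -> per-sample true allele fraction + label)."""

    def __init__(self) -> None:
        self.sites: dict[tuple[str, int, str, str], dict] = {}

    def add(self, key: tuple[str, int, str, str], sample: str, af: float,
            category: str, qual: float = TRUE_QUAL) -> None:
        entry = self.sites.setdefault(key, {"qual": qual, "carriers": {}})
        entry["carriers"][sample] = (af, category)


def simulate_experiment(
    config: SimulationConfig,
    genome: Sequence[GenomeSequence],
    samples: Sequence[SampleMeta] | None = None,
) -> ExperimentResult:
    """Generate one full truth-labelled experiment over ``genome``.

    The genome must already contain the planted target loci for every
    nuclease in the config (see :func:`simulate_reference`).  Deterministic
    given (config, genome): per-sample draws come from RNG streams keyed by
    (seed, sample_id).
    """
    samples = list(samples) if samples is not None else default_design(config)
    from .io import validate_metadata

    validate_metadata(samples)
    active = [s for s in samples if not s.excluded]
    by_group: dict[str, list[SampleMeta]] = {}
    for s in active:
        by_group.setdefault(s.experiment_group, []).append(s)

    for spec in config.nuclease_specs:
        if spec.on_target is None:
            raise ValueError(
                f"nuclease {spec.nuclease_id} has not been planted into the genome"
            )
    reserved = [spec.on_target for spec in config.nuclease_specs]
    reserved += [(p.chrom, p.pos, p.pos + 30) for p in config.planted_offtargets]
    space = _SiteSpace(genome, reserved)
    gdict = genome_dict(genome)
    events = _EventTable()

    def want_indel(rng: np.random.Generator) -> bool:
        return bool(rng.random() < config.indel_fraction)

    # 1. polymorphisms against the reference assembly: fixed in everyone
    rng = _rng(config.seed, "ref-polymorphisms")
    for _ in range(config.n_ref_polymorphisms):
        key = space.draw(rng, want_indel(rng))
        for s in active:
            events.add(key, s.sample_id, 1.0, "ref_polymorphism")

    # 2. private polymorphisms of each wild-type pedigree
    for group, members in sorted(by_group.items()):
        wt = next(m for m in members if m.role == "wildtype")
        rng = _rng(config.seed, wt.sample_id, "lineage")
        for _ in range(config.n_lineage_polymorphisms):
            key = space.draw(rng, want_indel(rng))
            for m in members:
                events.add(key, m.sample_id, 1.0, "lineage_polymorphism")

    # 3-5. per-plant events
    for group, members in sorted(by_group.items()):
        wt = next(m for m in members if m.role == "wildtype")
        siblings = [m for m in members if m.role != "wildtype"]
        for plant in siblings:
            rng = _rng(config.seed, plant.sample_id, "events")
            # fixed spontaneous mutations accumulated in culture
            for _ in range(rng.poisson(config.spontaneous_rate)):
                key = space.draw(rng, want_indel(rng))
                events.add(key, plant.sample_id, 1.0, "spontaneous")
                u = rng.random()
                if u < config.chimeric_echo_prob:
                    af = float(rng.uniform(0.05, 0.5))
                    events.add(key, wt.sample_id, af, "chimeric_spontaneous")
                elif u < config.chimeric_echo_prob + config.share_prob:
                    others = [m for m in siblings if m is not plant]
                    if others:
                        other = others[int(rng.integers(len(others)))]
                        events.add(key, other.sample_id, 1.0, "spontaneous")
            # subclonal (chimeric) mutations of the plant itself
            for _ in range(rng.poisson(config.chimeric_rate)):
                key = space.draw(rng, want_indel(rng))
                events.add(key, plant.sample_id, float(rng.uniform(0.05, 0.5)),
                           "chimeric_spontaneous")
            # PEG-treatment-induced mutations
            if plant.role in {"peg", "peg_dna", "edited"}:
                for _ in range(rng.poisson(config.peg_snv_mean)):
                    key = space.draw(rng, False)
                    events.add(key, plant.sample_id, 1.0, "treatment_induced")
                for _ in range(rng.poisson(config.peg_indel_mean)):
                    key = space.draw(rng, True)
                    events.add(key, plant.sample_id, 1.0, "treatment_induced")
            # the on-target edit itself
            if plant.role == "edited":
                spec = _spec_by_id(config, plant.nuclease_id)
                mode = C_NHEJ_MODE if rng.random() < config.c_nhej_prob else ALT_EJ_MODE
                chrom, pos, ref, alt = simulate_on_target_edit(
                    gdict, spec, mode, rng
                )
                events.add((chrom, pos, ref, alt), plant.sample_id, 1.0, "on_target")

    # planted off-target edits
    ot_rng = _rng(config.seed, "planted-offtarget-edits")
    for p in config.planted_offtargets:
        if p.edited_sample is None:
            continue
        seq = gdict[p.chrom]
        s0 = p.pos + 8 + int(ot_rng.integers(0, 4))
        ref = seq[s0 - 1:s0 + 4]
        events.add((p.chrom, s0, ref, ref[0]), p.edited_sample, 1.0,
                   "planted_off_target")

    # injected caller noise: low QUAL, subclonal AF, single carrier
    for s in active:
        rng = _rng(config.seed, s.sample_id, "noise")
        for _ in range(rng.poisson(config.noise_rate)):
            key = space.draw(rng, want_indel(rng))
            events.add(key, s.sample_id, float(rng.uniform(0.05, 0.3)),
                       "noise", qual=float(rng.uniform(0.0, 30.0)))

    return _render(config, genome, samples, active, events)


def _render(
    config: SimulationConfig,
    genome: Sequence[GenomeSequence],
    samples: list[SampleMeta],
    active: list[SampleMeta],
    events: _EventTable,
) -> ExperimentResult:
    """Turn true allele fractions into GT:DP:AD genotypes and truth rows."""
    order = {g.name: i for i, g in enumerate(genome)}
    depth_rngs = {
        s.sample_id: _rng(config.seed, s.sample_id, "depth") for s in active
    }
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)

    records: list[VcfRecord] = []
    truth_rows: list[dict] = []
    for key in sorted(events.sites, key=lambda k: (order[k[0]], k[1], k[2], k[3])):
        chrom, pos, ref, alt = key
        entry = events.sites[key]
        genos: dict[str, SampleGenotype] = {}
        for s in active:
            rng = depth_rngs[s.sample_id]
            dp = int(rng.negative_binomial(r, p_nb))
            carrier = entry["carriers"].get(s.sample_id)
            if carrier is None:
                genos[s.sample_id] = SampleGenotype(0, dp, dp, 0)
                continue
            af, category = carrier
            ad_alt = int(rng.binomial(dp, af)) if dp > 0 else 0
            genos[s.sample_id] = SampleGenotype(1, dp, dp - ad_alt, ad_alt)
            truth_rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "sample_id": s.sample_id, "category": category, "true_af": af}
            )
        records.append(VcfRecord(chrom, pos, ref, alt, entry["qual"], genos))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return ExperimentResult(list(genome), samples, records, truth)


# ---------------------------------------------------------------------------
# truth handling helpers
# ---------------------------------------------------------------------------

#: site-level precedence when carriers of one site have different labels
_TRUTH_PRIORITY = [
    "on_target",
    "planted_off_target",
    "treatment_induced",
    "spontaneous",
    "chimeric_spontaneous",
    "lineage_polymorphism",
    "ref_polymorphism",
    "noise",
]


def site_truth_labels(truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-(site, plant) truth rows to one label per site."""
    prio = {c: i for i, c in enumerate(_TRUTH_PRIORITY)}
    rows = []
    for (chrom, pos, ref, alt), sub in truth.groupby(
        ["chrom", "pos", "ref", "alt"], sort=False
    ):
        label = min(sub["category"], key=lambda c: prio[c])
        rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "site_id": f"{chrom}:{pos}:{ref}>{alt}", "category": label}
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "site_id", "category"]
    )
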