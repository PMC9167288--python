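# Methods

## The system being modelled

A clonal haploid plant (moss protonema) is dissociated into protoplasts;
single protoplasts regenerate into plants. Because each plant is a clone
of one cell, any real somatic variant should be *fixed* — present in
essentially all reads — while a mutation that arose after the first cell
division appears *chimeric*, at subclonal allele fraction. Three wild-type
pedigrees ("A", "B", "C") diverged over decades of independent culture:
they share many variants against the reference assembly and each carries
private ones. From pedigree A, four CRISPR-edited plants were regenerated
(two guides × two plants); from B, two TALEN-edited plants; from C, two
untreated controls, two PEG-only and two PEG+mock-DNA plants (one of the
latter excluded as contaminated, leaving 14 sequenced samples). The audit
asks: once polymorphism, spontaneous mutation and PEG-induced mutation
are accounted for, is anything left that the nucleases must explain?

## Off-target search

CRISPR queries are the 20-nt protospacer plus the 3-nt PAM, searched as a
23-mer over both strands with Hamming distance ≤ `max_mismatches`
(default 5), mirroring a global-alignment homology search of the whole
target sequence. Mismatches are counted uniformly across the query,
PAM included; a `pam_aware` mode (require NGG, count mismatches over the
protospacer only) is available behind a flag, since reasonable audits
differ on this point and neither convention is privileged here. Matching
is ungapped — the 5-mismatch criterion is substitution-based — and `N`
reference bases never match any query base (conservative: an ambiguous
window still costs mismatch budget). Reverse-strand hits are reported
with plus-strand window coordinates. A palindromic window can therefore
legitimately appear once per strand.

TALEN half-sites are each searched the same way; candidate cleavage sites
are *facing* pairs — upstream half-site bound on the plus strand,
downstream on the minus strand — whose inner gap lies in
[`spacer_min`, `spacer_max`] = [5, 50] bp, measured between the facing
inner edges (where the FokI dimer must assemble). All four identity
combinations (left/left, left/right, right/left, right/right) are
considered and each genomic pair is reported once with summed half-site
mismatches.

Predicted sites are crossed with observed variants using a ±50 bp window
by default, wide enough to catch the deletion spread that end-joining
repair produces around a cut.

## Filtering and the site matrix

Per-sample calls are retained iff `QUAL > 20`, `DP > 3` and more than one
read supports the alternate allele (all bounds strict). For retained
calls the haploid allele-fraction rule applies: VAF ≥ 0.8 is a fixed
variant; VAF in [0.05, 0.8) is chimeric (subclonal) evidence; below the
0.05 floor the call is treated as caller noise and the sample as
reference. The 0.05 floor is this package's own parameter (exposed as
`chimera_floor`): it separates genuine subclonal signal, which the
attribution tree uses as evidence, from the low-fraction artefacts every
caller produces.

The union of retained sites is assembled into an all-samples state matrix
(`fixed_alt` / `chimeric_alt` / `ref` / `uncovered`). A sample with no
call at a site is `ref` when its joint-genotyping depth there exceeds 3,
else `uncovered`. Sites uncovered in any non-excluded sample, and sites
with no fixed carrier at all (purely subclonal or noise), are moved to a
QC sidecar and never classified — the coverage-in-all-samples rule makes
presence/absence comparable across plants, at the cost of occasionally
discarding a real variant whose position happens to be thinly sequenced
in one unrelated sample. InDels are parsimony-trimmed at the VCF boundary
so cross-sample site matching is well defined (inputs are assumed
left-aligned, as joint callers and this package's simulator produce);
`|len(ref) − len(alt)| > 50` marks the large size class, which flows
through the same matrix rather than a separate caller.

## Attribution

The decision tree runs in a fixed precedence; the first matching rule
wins. "Carried" always means fixed (VAF ≥ 0.8) — chimeric states act only
as evidence and never enter counts:

1. fixed in every non-excluded sample → **reference polymorphism**;
2. fixed in exactly one pedigree (wild type and all plants derived from
   it, absent elsewhere) → **lineage polymorphism**;
3. carried by an edited plant within its own nuclease's target window
   (target span ± 50 bp) → **on-target**;
4. carried by an edited plant within ±50 bp of a predicted off-target
   site of its own nuclease → **predicted off-target hit**;
5. carried by ≥2 independently regenerated plants of one group, or fixed
   in a plant while chimeric in its matched wild type, or carried by an
   untreated control → **spontaneous** (cross-group sharing short of
   all-samples is also spontaneous, flagged `cross-group`: two pedigrees
   sharing a variant points to culture ancestry, not treatment);
6. carried only by PEG-exposed plants (PEG, PEG+DNA or edited) →
   **treatment-associated**;
7. otherwise **unattributed**.

Placing lineage polymorphism above the positional rules is deliberate: a
variant fixed through an entire pedigree cannot be a nuclease product,
however close it sits to a predicted site. The known ambiguity of this
scheme is the singleton variant in a PEG-exposed plant: a genuine
spontaneous mutation with no echo and no sharing is indistinguishable
from a treatment-induced one and lands in `treatment_associated`; truth-
recovery scoring therefore treats those two labels as an acknowledged
confusion pair, while polymorphism and on-target labels are scored
strictly.

Per-plant count tables include fixed variants of categories 3–7 (never
polymorphisms), split into SNVs and InDels, matching how per-plant
mutation loads are tabulated against each matched wild type.

## Repair signatures

For a deletion with span *(s, e)* in reference context, the junction
microhomology is the largest *m* for which the *m* bases before the span
equal the span's last *m* bases, or the span's first *m* bases equal the
*m* bases following it — the two equivalent placements of a
microhomology-collapsing deletion — capped at the deletion length. The
symmetric (two-sided) definition is used because left- and right-aligned
representations of the same deletion must score identically.

Classification: a pure deletion with microhomology ≥ `min_mh` (default
2 bp; a 1-bp "microhomology" carries no signal) is **Alt-EJ-compatible**;
a net deletion that needs exactly one junction substitution — complex
indels are first decomposed into one contiguous deleted block plus
retained-sequence mismatches, taking the placement with fewest
substitutions and, on ties, the largest microhomology — is
**Alt-EJ with substitution**; insertions and everything else are
**C-NHEJ-like**.

## The synthetic-experiment generator

The generator emulates the study design, not sequencing reads. Defaults
are the package's study-scale conditions:

| parameter | default | basis |
|---|---|---|
| chromosomes | 150/100/60 kb | desk-scale stand-in with unequal lengths, so length-proportionality is testable |
| shared reference polymorphisms | 300 | scaled-down analogue of the dominant shared-variant class |
| private polymorphisms per pedigree | 60 | pedigrees must be separable from treatments |
| spontaneous rate / plant | 1.0 | untreated controls carry ~0–3 mutations |
| chimeric rate / plant; echo prob.; sharing prob. | 0.5; 0.3; 0.15 | subclonal echoes and sibling sharing are the evidence rules 5 relies on |
| PEG-induced SNVs / InDels per exposed plant | Poisson(15) / Poisson(19) | observed PEG-plant counts (20/10/16 SNVs, 19/19/24 InDels) |
| depth | NB(mean 25, dispersion 8) | middle of the reported 14–39× range; overdispersion deliberately stresses the DP > 3 filter |
| allele depth | Binomial(DP, true AF) | haploid clone model |
| QUAL | 60 true / U(0, 30) noise | puts the QUAL > 20 boundary under test without modelling a caller |
| noise calls / sample | Poisson(10), AF U(0.05, 0.3) | exercises all three hard filters |

Target loci are written into the genome exactly (protospacer+PAM with the
cut 3 bp from the PAM; TALEN half-sites around a 16-bp spacer with the
cut mid-spacer), with a 3-bp microhomology pair embedded flanking each
cut so Alt-EJ outcomes exist by construction. On-target edits draw the
microhomology-collapsing deletion that maximises junction microhomology
within ±12 bp of the cut (C-NHEJ events, a 1–3 bp cut-site indel, occur
with probability 0.25 per edited plant). Optional planted off-targets add
a degenerate copy of a query elsewhere in the genome, optionally carrying
a true edit in one edited plant.

Every emitted alternate call carries exactly one truth label
(`ref_polymorphism`, `lineage_polymorphism`, `spontaneous`,
`chimeric_spontaneous`, `treatment_induced`, `on_target`,
`planted_off_target`, or `noise`), and the VCF/truth pair is conserved in
both directions. RNG streams are keyed by `(seed, sample_id, purpose)`,
so adding a sample leaves the other samples' draws untouched, and a fixed
`(config, seed)` reproduces byte-identical outputs.

What the generator does **not** model: read-level errors, mapping bias,
GC-coverage structure, linked or structural events, or a realistic QUAL
distribution. Passing truth-recovery tests therefore demonstrates the
correctness of the filtering/attribution logic under the stated noise
model, not robustness to alignment artefacts in real data.

## Numerical and statistical choices

- Mutation efficiency is `100 × resistant/regenerants` reported to two
  decimals; count aggregation uses exact rational arithmetic (integer
  sums, `Fraction` means), so two-decimal reporting carries no float
  drift. An empty strategy's mean is undefined (absent), never 0.
- Kruskal–Wallis uses an exhaustive permutation null whenever the pooled
  sample is ≤ 8 observations (groups here have 2–6 plants; the chi-square
  approximation is poor there), with midranks and the standard tie
  correction, and scipy's tie-corrected asymptotic test otherwise. Note
  the granularity floor of the exact null: with groups of 2+2+2 the
  smallest attainable p is 1/15 ≈ 0.067, so "significance" at α = 0.05
  is unreachable no matter how separated the groups are; α is an explicit
  parameter (default 0.05) for this reason.
- Spearman correlation comes from scipy; at least three chromosomes are
  required.
- Coordinates are 0-based half-open internally; VCF (1-based) and BED
  (0-based) convert at the I/O boundary only.

## Known limitations

- The coverage-in-all-samples rule interacts with the overdispersed depth
  model: ~0.1% of sample-site depth draws fall at DP ≤ 3, so a large
  experiment occasionally loses a real site (including, rarely, an
  on-target edit) to the QC sidecar. This is faithful to the audited
  pipeline's behaviour; the sidecar makes the loss visible.
- Singleton spontaneous mutations in PEG-exposed plants are
  systematically attributed to treatment (see above) — an identifiability
  limit of the design itself, not of the implementation.
- The homology search is exhaustive within its ungapped, fixed-length
  model; bulged (gapped) off-target sites and activity scoring are out of
  scope.
- Large-InDel detection relies on the input VCF already containing such
  records; no split-read evidence is re-examined.
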