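# Methods

This note records the models behind `kdrcall`, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Genotype model

Genotypes are unordered diploid allele pairs at the sodium-channel residues
989 {S, P}, 1016 {V, I, G} and 1534 {F, C} (*Musca domestica* numbering
throughout; no remapping to *Ae. aegypti* transcript coordinates).
Shorthand strings concatenate the pairs in locus order, each pair printed
in a per-locus canonical order (989 S<P; 1016 V<G<I; 1534 F<C) inferred
from how field reports print genotypes ("VGFC", "GIFC", "SPGIFC").  The
canonical order is data on the `Locus` object, not code, because nothing
guarantees it generalises to other loci.  A 4-letter string covers
1016/1534 only and leaves 989 *unknown* — deliberately not "SS", since
melt-curve workflows typically do not assay 989.

Ensemble classification: a genotype carrying any Indopacific allele (1016G
or 989P) together with 1016I is `mixed`; otherwise G/P ⇒ `indopacific`;
otherwise ≥1 I with ≥1 C ⇒ `western_hemisphere`; VV+FF with SS-or-unknown
989 ⇒ `susceptible_like`; anything else `other`.  The rule is total and
single-valued over all 54 complete genotypes (tested exhaustively).

## Melt-curve calling

A derivative melt curve is modelled as nonnegative values on a strictly
increasing temperature grid (default 70–95 °C at 0.05 °C).  Peak detection
smooths with a centred 5-point moving average, takes local maxima with
height and prominence at least 20 % of the global maximum (`min_rel_height`,
configurable; an absolute floor of 0.05 derivative units rejects flat
curves), keeps at most three peaks, and refines each apex off-grid by
parabolic interpolation — so a symmetric peak's Tm is recovered to well
under one grid step, and translating a curve translates the estimates
exactly.

Calling follows the control-window rule: a peak is assigned to the
observable class whose control Tm lies within ±0.3 °C (inclusive; nearest
control wins if two qualify, with a warning).  One assigned class is a
homozygous pattern, two a heterozygous pattern, none a no-call.  Control
Tm values are run data, never constants: `AssayDefinition.class_tms` maps
each class to the Tm(s) of its control wells, and a class may carry several
(the run includes a control for *every* allele, so the V-like class of the
V1016I assay is anchored by both the V and the G control wells).

The packaged fixture Tm table encodes the two measured behaviours — in the
V1016I assay the G product melts 0.2 °C above V, inside the window, hence
unseparable; in the V1016G assay the I product melts 0.8 °C below V — and
places everything else at invented but documented positions (V1016I: V
79.0, G 79.2, I 81.0; V1016G: V 84.0, I 83.2, G 80.0; F1534C: F 86.0,
C 84.5).  The I product of the V1016I assay sits 1.8 °C from the V-like
controls so the two call classes are genuinely separable, which is what the
assay's successful routine use implies.  One consequence worth knowing: a
+1.0 °C instrument drift in the V1016G assay silences the V and G products
(no control within window) but *aliases the I product onto the V control*
(0.8 − 1.0 = −0.2 °C away), so drifted II samples keep reading non-G; the
within-tolerance drift of ≤ 0.3 °C changes nothing.

Run validation mirrors bench practice: every homozygous control must yield
exactly its class and the negative a no-call (failures invalidate the run);
a failed heterozygous control — e.g. a degraded G template dropping its
peak — downgrades the run to `valid_with_warning` rather than invalidating
it, since homozygous calls remain interpretable.

## Assay confusability and resolution

Each assay is a total map from alleles to observable classes
(`VirtualAssayModel`): V1016I sends {V, G}→V-like, I→I; V1016G sends
G→G, {V, I}→non-G; the AS-PCR sends V→strong V band, I→weak V band
(off-target amplification), G→G band.  An observation constrains the
genotype to the set of diploid pairs whose predicted outcome matches it
(MCA: class-set equality; AS-PCR: band compatibility; Sanger: a two-symbol
call pins the genotype, a single legible symbol only asserts presence).
`resolve_1016` intersects constraint sets across methods: a singleton is
resolved, an empty intersection is a conflict (the minimal conflicting
method pair is named), and monotonicity — more observations never enlarge
the candidate set — holds by construction.

Two band-semantics choices: an **absent** AS-PCR band excludes nothing by
default, because real tables show true heterozygotes with single bands
(band dropout); a strict mode is available.  A **weak** V band means "V or
I present", encoding the observed off-target amplification; any G band
means G present.

The joint outcome map of the two 1016 MCAs is injective over all six
diploid genotypes — proven exhaustively in the tests — so running both
always determines the genotype.  Each assay alone collides its blind
homozygote triple ({VV, VG, GG} for V1016I, {VV, VI, II} for V1016G) *and*
its two heterozygote patterns ({VI, GI}, resp. {VG, GI}): a het pattern
proves the unambiguous allele but leaves the partner allele open.

An allele is **confirmed** when it is present in every candidate genotype
and was detected through its own dedicated signal (its own class, band or
base call) by at least two distinct methods (threshold configurable).
The resolver trusts observations, not labels: a mislabelled control
resolves cleanly to what the methods actually saw, and the conflict
machinery is reserved for genuinely contradictory observations.

## Amplicon-read genotyping

Reads pass a mean-Phred ≥ 10 filter (read-level mean, Phred+33 only;
out-of-range quality characters are refused, never reinterpreted).
Demultiplexing requires the barcode flank construct to align at *each* read
end with more than 37 aligned bases at more than 95 % identity (either
orientation per end); reads matching zero or several barcodes go
unassigned.  "Aligned length" is the number of base-to-base alignment
columns — the natural reading for an alignment-based rule.

Alignment is internal: for each read, every panel reference is tried on
both strands; the shorter sequence is aligned semi-globally inside the
longer (so both full-amplicon reads with barcode flanks and bare amplicon
substrings place correctly) under bit-parallel edit distance, and the
optimal path is then *scored* under a documented affine scheme (match +2,
mismatch −4, gap open −4, extend −2; a gap of length k costs
−4 − 2(k−1)).  Alignments scoring below 40 % of read length × match score
are discarded — an empirical-null test confirms random 500-mers never
reach the floor.  Identity is matches over aligned columns including
internal gaps, excluding end gaps.  At the ≤ 10 % divergence this pipeline
sees, the edit-distance path and the affine-optimal path coincide; a unit
test checks the reported score against an independent affine local aligner
on substitution-only reads.

Codon pileups count the read 3-mer over each annotated codon, sense-strand
oriented, from reads spanning all three positions without a gap.  Genotype
calling translates codons to alleles and applies fraction thresholds:
homozygous at top-allele fraction ≥ 0.80, heterozygous at top-two ≥ 0.20
each, otherwise a reasoned no-call (`low_coverage` below 100×,
`unknown_codon` when unattributable codons exceed 0.20, else
`ambiguous_fraction`).  A codon absent from the table is attributed to the
unique nearest allele codon within one substitution (configurable, 0
disables); ambiguous or more distant codons pool as `other`.  This is the
algorithmic counterpart of reading a pileup by eye, where one miscalled
base does not unseat the evident codon — with exact-3-mer pooling, 5 %
per-base error puts ~14 % of a homozygote's codons in `other` and the
0.80 threshold sits inside the binomial noise band, which no visual reader
would accept.  The 100× rule applies per amplicon (including COI), and a
sample is excluded whenever any amplicon falls below it.

Species verification: per-column majority consensus (ties → N) over the
COI reference interval covered at ≥ 100×, matched end-gap-free against a
local reference set; pass at ≥ 99 % identity, low-confidence flag when the
consensus is shorter than half the reference.

The packaged panel is synthetic: real codon tables (989 TCC/CCC,
1016 GTA/ATA/GGA, 1534 TTC/TGC) at annotated positions inside
random-at-fixed-seed flanks (M1 420 bp, M2 650 bp, M3 400 bp, COI 658 bp —
bracketing typical kdr/COI amplicons), with synthetic-accession COI
references (two *Ae. aegypti* haplotypes and a ~12 %-divergent congener
stand-in).  Users supply real references as FASTA + JSON.

## Synthetic-data generators

Melt curves are sums of one Gaussian per distinct allele product (width
0.25 °C; centres jittered N(0, 0.1 °C); heights 1.0 ± 20 %; white noise
0.01), with optional class-level dropout.  Width 0.25 keeps the 0.8 °C
V/I product pair resolvable as two peaks, as the underlying chemistry
requires; heterozygote peak heights equal homozygote heights up to jitter,
an assumption, since relative heights are not characterised.

Cohorts are Hardy–Weinberg draws.  In linkage mode whole haplotypes are
sampled: the 1016 allele first (defaults V 0.15 / I 0.80 / G 0.05,
emulating a Western-Hemisphere population with a rare introgressed G);
1534 is then C on I haplotypes, F on G haplotypes (the strong
unidirectional linkages), Bernoulli(0.8 C) on V haplotypes; 989 is P only
on G haplotypes (probability 0.5).  Consequently 1534F is rare and G
carriers always carry F — the premise of reflex screening.

Reads: per amplicon, a binomial haplotype split at the configured depth
(default 200×), substitution/insertion/deletion errors at 5 %/0.5 %/0.5 %
(Nanopore-like magnitude, uniform — no homopolymer structure), barcode
flanks at both ends with 1 % substitution error, random strand, constant
quality string encoding the total error rate (Q12).  Observation records
apply the virtual assay models plus configured dropout; the two simulated
1016 MCA patterns are combined exactly as an analyst combines them — by
constraint intersection — which reproduces both correct calls and the
instructive failure mode where a G template dropping out of both 1016
assays makes a true G/I heterozygote resolve cleanly, but wrongly, to II.

What passing tests on these generators do **not** show: robustness to
basecaller-specific error structure (homopolymers, chimeras), melt-curve
baseline drift or dye chemistry, plate effects, or real population
structure; the generators emulate the statistical shape the calling rules
assume, not an instrument.

## Problem sizes and numerics

The heavy parameter-recovery test runs 200 simulated samples cycling all
54 genotypes at 200× and 5 % substitution error (≥ 99 % exact 6-letter
recovery, ~1 minute); the melt-curve accuracy test uses 1 000 curves; the
Tm-offset estimate averages 100 curve pairs (mean-of-differences standard
error ≈ 0.014 °C against the ±0.05 °C check).  The window-boundary
comparison uses a 10⁻⁹ guard so ±tolerance is inclusive under floating
point.  Ties: peak-to-class assignment prefers the nearest control
(warning attached when two qualify); consensus base ties give N; alignment
candidates tie-break deterministically by panel order and strand, making
identical seeds byte-identical end to end.

## Known limitations

No nucleotide-level haplotype phasing (dried field samples preclude
transcript isolation, and the pipeline never links loci across amplicons);
no probabilistic genotype likelihoods — the logic is deliberately
set-valued; no gel-image or chromatogram signal processing (AS-PCR and
Sanger enter as read observations); no SAM/BAM emission; the AS-PCR weak/
strong distinction is consumed as data, with no intensity model behind it.
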