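# Methods

## Setting and model

`mitodiff` analyses two or three complete, circular-mapping plant
mitogenomes from closely related species (noncoding divergence on the
order of 10⁻³–10⁻² substitutions/site) together with a plastome and,
optionally, a nuclear genome and a small external mitochondrial
reference collection. The working model of mitogenome size evolution is
additive: the sequence content that cannot be aligned between a species
pair decomposes into chloroplast-derived transfers (CP), extra copies
arising from intragenomic duplication (ID), gain or loss of
mitochondrial sequence along the phylogeny (GL), putative horizontal
acquisitions from distant plants (PH), nuclear-homologous sequence (NU)
and an unexplained residue (ND). A three-taxon rooted tree ((C,S),D) is
assumed wherever polarity matters (lineage assignment of substitutions,
gain-versus-loss parsimony); C and S are the ingroup cherry and D the
early-diverged outgroup.

## Pairwise comparison

Local similarity comes from NCBI BLASTN run with word size 11,
low-complexity filtering disabled, percent-identity threshold 85 and
hits shorter than 90 bp discarded. Identity is matches over alignment
columns, gap columns included — the conventional percent identity of
the search tool. Circular sequences are searched against a
concatenation-doubled subject; hits are deduplicated modulo the subject
length, including hits that are modular sub-alignments of a larger
junction-crossing hit (without this, one locus near the rotation origin
is counted twice and downstream copy counts are wrong).

Hits are chained into collinear blocks by dynamic programming: chains
must be strand-uniform, non-overlapping and coordinate-monotone in both
genomes, with inter-anchor gaps at most `max_gap` (default 1,000 bp,
the granularity of organelle rearrangement we aim to resolve); chain
score is anchored bp minus 0.05 per gap bp, ties broken leftmost.
Chains are extracted best-first under a one-to-one constraint: a chain
that would re-use more than half of the query or subject sequence
already claimed by a better block is dropped. The constraint is what
makes the extra copy of a duplicated segment *non-alignable* — the
behaviour of a locally-collinear-block decomposition — and it is why
duplications are classifiable at all.

Non-alignable regions are the per-genome complement of the union of
*hit* intervals (not block spans: a chain may legitimately bridge an
unaligned insertion shorter than `max_gap`, and that insertion must
still count as non-alignable). Complement intervals separated by less
than 50 bp of covered sequence are merged and regions shorter than
90 bp discarded; the 90 bp floor deliberately matches the hit-recording
threshold so that sub-threshold gaps and regions partition the genome
exactly. On circular genomes a region spanning the linearization origin
is re-joined, so region length multisets are rotation-invariant. Each
genome of a pair is used as the query once, making the operation
symmetric under role swap by construction. Inversions are reported as
minus-strand blocks above a span threshold (default 1 kb).

## Chloroplast transfers and pseudogene calls

Transferred regions are the merged union of qualifying mt-vs-plastome
hits on the mitochondrial axis; totals are computed on the union so
overlapping hits are never double-counted. One copy of the plastome
inverted repeat (the largest inverted pair ≥1 kb) is removed before
searching; a flag restores full-length behaviour. Gene copies inside a
region are located by projecting the plastome CDS annotation through
the region's hits (with a ±60 bp margin absorbing alignment drift)
rather than re-annotating — annotation is an input, not a deliverable.
A projected copy is *intact* iff it aligns over ≥95% of the reference
CDS with no frame-disrupting indel (length not a multiple of three) and
no internal stop codon; otherwise the cause reported is the first
lesion in reference-coordinate order, with precedence frameshift <
premature stop < truncation when coincident. The 95% coverage threshold
and the precedence order are package decisions; copies with more than
5% ambiguous bases are refused rather than guessed.

## Origin attribution

Attribution is per base with fixed precedence CP > ID > GL > PH > NU >
ND, so the six category totals always sum exactly to the region length
(asserted on every call). The cascade: (1) bases hit by the species'
own plastome are CP; (2) among the rest, bases covered by more hits in
the region's own mitogenome than in the partner's (partner ≥ 1) are ID;
(3) bases absent from the partner but present in the third species are
GL; (4) remaining bases are searched against the external mitochondrial
collection and the species' own nuclear genome — a distant-taxon best
bitscore exceeding 1.1× the close-taxon best makes PH (the margin makes
the qualitative "scores higher with distant taxa" criterion
deterministic), a nuclear hit makes NU, annotated as a probable
mitochondrion-to-nucleus transfer when mitochondrial hits corroborate;
(5) the residue is ND. Removing the external collection can only move
PH bases into NU/ND, never disturb CP/ID/GL — a property the tests
enforce.

Gain-versus-loss polarity of a presence/absence pattern is decided by
exhaustive minimal-event enumeration over all root and internal-node
state assignments on ((C,S),D); distinct minimal solutions mean
*ambiguous*. Note that a region present only in the outgroup D is
ambiguous (a gain in D ties with a single loss on the (C,S) stem), not
a gain — only the two cherry taxa admit unambiguous single-gain calls.

## Repeats and recombination

Dispersed repeats are enumerated as *exact* maximal repeated segment
pairs (both strand relations, ≥30 bp) by word seeding and unbounded
extension; exactness is deliberate, because it admits a brute-force
quadratic oracle that the tests run on ≤5 kb genomes. Repeat units are
selected greedily, longest first, skipping pairs whose copies are
already contained in accepted units — the masking behaviour of the
classic organelle repeat-unit scripts. Repeat content is the union of
all copies over genome length (union, not sum: overlapping copies are
not double-counted; the choice is stated in output headers).

The recombination assay counts long reads by conformation. With repeat
copies 1 and 2 flanked by unique sequence A‥B and C‥D, a read counts
iff it contains one full repeat copy plus ≥100 bp of flank on both
sides at ≥80% identity, and it is assigned the best-matching of A-R-B,
C-R-D (parental) or A-R-D, C-R-B (recombinant); ties between a parental
and a recombinant assignment are discarded. Frequency is recombinant
over total spanning reads, undefined at zero total; copies closer than
two flank lengths refuse the assay. Reads are sorted by identifier
first, so the counts are order-invariant.

## Divergence, rates, clock

Substitutions and indels are tabulated from the affine-gap alignments
the search engine itself produces for each hit (a unit-cost aligner is
only a fallback: with unit costs a substitution inside a repeat
motif is representable as a deletion–insertion pair, which silently
corrupts substitution counts). Each mismatch column yields one record
with transition/transversion class, CDS/intron/intergenic context and,
in CDS, the codon effect computed strand-aware from the anchor codon;
each gap run yields one indel with its length.

Noncoding distance uses the Kimura two-parameter correction,
d = −½ln(1−2P−Q) − ¼ln(1−2Q), defined only while both logarithm
arguments are positive (saturation raises an explicit error).
Synonymous and nonsynonymous rates use weighted pathway counting:
per-codon site counts weight transitions by an exposed `kappa` (default
1) and exclude changes that would create a stop codon from the
bookkeeping; differences between codon pairs are averaged over minimal
substitution pathways, excluding pathways through intermediate stops
when an alternative exists; each class is then corrected with the same
two-parameter formula. Lineage polarization assigns a C–S difference to
the lineage whose base differs from the state shared by the outgroup
and the other ingroup genome; three-state columns and columns without
outgroup coverage stay unpolarized, and lineage counts plus unpolarized
always equal the total.

The clock is deliberately simple: rate = calibration distance /
calibration time, T = query distance / rate, with *no* factor of two by
default — the pairwise-distance-over-pairwise-rate convention (1.33×10⁻³
against a 6.28×10⁻²/88 Ma calibration gives 1.86 Ma, and the same
convention returns the 7.15×10⁻¹⁰ and 2.39×10⁻⁹ per-site-per-year
rates). A `per_lineage` flag switches to T = d/2r for users who prefer
the 2T convention. The estimate carries no confidence interval; it
inherits all the assumptions of a strict clock and of the calibration
point.

## Recurrent transfers

A recurrent transfer overwrites part of an old transferred region with
a fresh chloroplast copy, so the region becomes chimeric. Detection
works on a multiple alignment (MAFFT) of the region's mitochondrial
copies from several species, at least one chloroplast counterpart, and
the query individual's copy. *Diagnostic* columns are those where the
chloroplast state differs from the majority consensus of the non-query
mitochondrial copies; columns containing any gap among the compared
sequences are excluded from scoring and reported separately. The scan
evaluates every inter-column boundary in both orientations —
score(b) = agreeing diagnostic sites left of b (chloroplast side) plus
agreeing sites right of b (mitochondrial side) — and keeps the maximum,
leftmost on ties; the verdict is chimeric only if the best two-segment
score strictly beats the best single-segment (all-chloroplast or
all-mitochondrial) explanation. The scan is itself exhaustive, so the
oracle test asserts tie-breaking determinism, and localization error is
bounded by the local diagnostic-site spacing. A single breakpoint is
assumed.

Verification trees are neighbor-joining on pairwise K2P distances
(pairwise gap deletion; saturated pairs get a large finite distance)
for the two partitions separately, with nonparametric bootstrap over
columns (default 1,000 replicates) supporting the
query-with-chloroplast bipartition. NJ with bootstrap replaces a full
maximum-likelihood search because the acceptance property is the
clustering pattern, not likelihoods, and NJ is fast and deterministic
given the seed. The fixation survey scans each individual and counts a
carrier only when its boundary falls within ±5 diagnostic sites of the
template carrier's.

## The simulator

The generator is the package's ground-truth instrument, not a fixture.
It evolves one random ancestor down ((C,S),D) with per-branch
substitution processes (transition weight `ts_weight`; the default 1.0
gives the neutral 1/3 transition fraction, i.e. a transversion-rich
spectrum, and the weight is exposed for users who want a stronger
transition bias) and short indels (1–8 bp) confined to noncoding
sequence. Default branch lengths
(C = S = 2.2×10⁻³, stem = 4×10⁻⁴, D = 2×10⁻³ noncoding
substitutions/site) reproduce ingroup noncoding divergence of
~4.4×10⁻³ and ingroup–outgroup divergence of ~4.6×10⁻³; coding sites
evolve 3-fold slower (`coding_rate_factor` = 1/3); the default event
inventory plants one ancestral ~5 kb chloroplast transfer (aged with
2.4% post-transfer substitutions and ~0.8% indels, so the old transfer
carries realistic diagnostic divergence from the extant plastome), one
~8 kb young transfer on D, two gains on the stem, one loss each on C
and S, a duplication, a foreign-donor insertion, a nuclear-homologous
segment, a large inversion, two dispersed repeat pairs and one
recurrent transfer covering ~2/3 of the ancestral region, carried by a
third of simulated individuals.

Placement is uniform with 100 bounded retries; duplication source
intervals are tracked and loss targets are reserved on the ancestor, so
no two events can silently confound each other (sibling-branch losses
deleting overlapping segments would otherwise turn two gain/loss
regions into one unclassifiable residue). Genomes are emitted at a
random rotation recorded in the ledger, which forces every downstream
stage to be rotation-tolerant. Long reads are drawn with a truncated
normal length distribution and a uniform substitution error model
(explicitly *not* a platform error profile); a configurable fraction of
repeat-spanning reads is converted to the recombinant conformation by
continuing into the other copy's downstream flank.

What the simulator does not emulate: tandem repeats, heteroplasmy,
recombination-driven structural dynamics beyond single planted events,
realistic long-read error profiles (indel-dominated), base composition
bias, and transfer donors other than the supplied references. Passing
tests therefore demonstrate correctness of the decomposition machinery
under the stated model, not robustness to every artefact of real data.

## Problem sizes and numerical choices

Tests and the reproduction script run the full event inventory on a
compact profile (16 kb mitochondrial ancestor, 10 kb plastome,
proportionally scaled events); this is the package's standard quick
profile, and the algorithms are identical at full organelle scale —
only search time grows. The reproduction script measures
origin-attribution accuracy over five simulated trios and the other
estimators at the sizes printed in its output. Degenerate inputs are
handled by refusal rather than guessing: empty plastomes, saturated
distances, assays on too-short or too-close repeats, alignments without
diagnostic columns and ambiguous gene copies all raise typed errors.
Ties are broken deterministically everywhere (leftmost coordinate, or
discard when a parental/recombinant tie cannot be resolved), and every
randomized procedure takes an explicit seed, so fixed-seed runs are
byte-identical — the pipeline writes a checksum manifest to make this
checkable.

## Known limitations

The block decomposition approximates a locally-collinear-block model
with fixed thresholds, so region boundaries carry ±tens-of-bp
granularity; copy counting for ID uses qualifying-hit counts, which
saturate for very high copy numbers; the PH margin rule (1.1×) is a
deterministic stand-in for a qualitative criterion; whether a region's
total should count hit unions or summed hit lengths is resolved as
union and flagged in outputs; and the clock provides a point estimate
only. Classification fidelity degrades when donor classes are less than
~10% diverged from each other, since the cascade then attributes on
near-equal scores.
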