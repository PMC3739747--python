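# Methods

This note documents the models, heuristics and numerical choices behind
`mitocomp`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate model

Genomes are circular. Internally every feature is stored 0-based
half-open on the heavy strand; report output converts to 1-based
inclusive to match GenBank convention. A feature crossing the circular
origin is kept whole and flagged `wraps_origin` (its numeric `end` is
then smaller than its `start`); linearization happens only at sequence
extraction, so true gene lengths are preserved. Light-strand features
are extracted as the reverse complement of the heavy-strand slice, so
`extract_gene` always returns the 5'→3' coding sense. Gene names are
normalized through a packaged, editable synonym table
(`data/gene_synonyms.tsv`) because GenBank naming varies across
submitters. IUPAC ambiguity codes other than N are rejected on input:
the downstream codon statistics assume a 4-letter alphabet, and N is
tolerated but excluded from all composition denominators.

## Composition statistics

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed from the
same counts as the composition percentages. Report rounding is half-up
(1 d.p. for composition, 2 d.p. for skew) with binary float noise
absorbed six places below the target precision; internal values keep
full precision.

All translation uses the vertebrate mitochondrial code (NCBI table 2):
AGA/AGG are stops and TGA is tryptophan, so the standard code would
miscount both stop validation and synonymous sites. Codon-position
composition drops incomplete terminal codons and reports the 12
heavy-strand protein genes pooled and ND6 (the only light-strand CDS)
separately — third-position anti-G (heavy) versus anti-C (light) is a
strand-specific property and pooling would average it away.

Incomplete stop codons cannot be read off the sequence alone; the
operational rule used here is: CDS length mod 3 ∈ {1,2}, terminal
residues T or TA, and a same-strand tRNA beginning within 2 bp
downstream. Such messages are completed to TAA by post-transcriptional
polyadenylation.

## Structural annotation

**Tandem repeats (ETAS).** A seed-and-extend detector compares the
sequence against itself shifted by each candidate period (default
5–150 bp), extending while the running mismatch fraction stays within
0.2 per unit; the tract endpoint maximizes matches − 4·mismatches so
tracts do not creep into flanking sequence, and overlapping calls at
different periods resolve greedily by length (ties to the smaller
period). This is deliberately not a reimplementation of a
scoring-based repeat finder: correctness is judged by ground-truth
recovery on synthetic repeats, not score equality. Each unit is tested
for the TAS motif TACAT and its reverse complement ATGTA; a tract
carrying both is flagged hairpin-capable, since TAS/cTAS pairing forms
the stable hairpins thought to signal replication termination.

**Conserved sequence blocks.** Each block is located as the best
(leftmost-minimum) Hamming-distance window for its consensus — no gaps
— and reported when mismatches ≤ ceil(tolerance × length). The default
tolerance of 0.2 per block reflects reported cross-taxon block
identities in the 81–95% range; at tolerance 0 the scan is provably
equivalent to exact substring search. Domain boundaries follow the
block architecture: ETAS runs from the CR 5' end to CSB-F (which
demarcates the central conserved domain), the CCD spans CSB-F..CSB-A,
and the downstream segment holds CSB-1..3. When CSB-F is absent the
ETAS 3' limit is undefined and reported as the CR end. Out-of-order or
overlapping best hits are both reported, with a warning rather than a
hard error. Consensus derivation is column-wise majority over non-gap
characters, ties broken by the fixed order A<C<G<T and flagged.

**O_L stem-loop.** Hairpin candidates (stem 5–12 bp, arms reverse
complementary with ≤1 mismatch, loop 3–16 nt) are scored by
(stem pairs − mismatches) × (1 + stem GC fraction) + loop T fraction,
rewarding the GC-rich stem and T-rich loop characteristic of the
light-strand origin. The conserved GCCGG motif is sought within 5 bp of
either stem base, and the pyrimidine fraction of the 10 bp 5' flank is
recorded.

**tRNA cloverleaf heuristic.** Acceptor stem: the 7 terminal bases of
each end, ≥6 pairs. Anticodon arm: a 5-pair stem around a 7-base loop,
chosen among candidates by fewest stem mismatches and then proximity to
the sequence midpoint; the anticodon is loop positions 3–5, reported in
RNA sense. D- and T-arms are any qualifying hairpin in the regions
flanking the anticodon arm. A cloverleaf requires acceptor + anticodon
arms plus at least one of D/T; a missing D-arm is reported as the
truncated cloverleaf typical of metazoan tRNA-Ser(AGY). This is a
plausibility heuristic, not a covariance-model scanner: borderline
cases are reported, not rejected, and on heavily diverged input the
anticodon-arm choice can be ambiguous (the T-arm has the same 5+7+5
shape by construction).

**Supernumerary tRNAs.** Any tRNA beyond the canonical 22-gene
complement (identified by neighbour context against the canonical gene
order) is globally aligned (match +1 / mismatch −1 / gap −2; identity =
matches / alignment columns) to every other tRNA in the same genome.
Best match adjacent at ≥70% identity → tandem duplication with
anticodon shift; extra copy inside the CR matching a distal gene →
long-range duplication into the CR; anything else is reported as
`none` and flagged for review. The 70% default sits below the 76–97%
identities of the events this detector is designed for, but well above
the background identity of unrelated tRNAs; the exact alignment
parameters are a package decision, since no standard exists.

## Divergence and selection

Pairwise identity uses global alignment (NT: match +1 / mismatch −1 /
open −4 / extend −1; AA: uniform +1/−1, same gaps) with gap columns
counted in the denominator — this penalizes indel-rich regions such as
the control region consistently; a flag can exclude them. Variable
sites are columns with ≥2 distinct non-gap characters, over columns
with ≥1 non-gap character.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
(changes to stop codons excluded from the per-position denominators),
site totals averaged over the two sequences, difference counts averaged
over all minimal mutation pathways between differing codons with
stop-codon intermediates excluded (re-admitted only if every pathway is
blocked), and Jukes–Cantor correction d = −3/4 ln(1 − 4p/3) applied to
both proportions. The ratio is undefined (reported missing, excluded
from means) when Ks = 0 or a proportion reaches 3/4; codons containing
N or alignment gaps are skipped. Pathway counting is verified against
an exhaustive enumeration oracle over all codon pairs to 1e-12.

Per-gene summaries are means ± sd over all n(n−1)/2 unordered genome
pairs, not over genomes. Multiple alignment of equal-length inputs is
the identity; unequal-length inputs go through MAFFT (`--auto`), with
CDS aligned as amino acids and gaps back-threaded in codon triples.
The topology check concatenates the 12 heavy-strand protein genes —
ND6 is excluded from concatenation (fast evolution invites homoplasy)
but kept in per-gene statistics — computes p-distances, runs
neighbour joining, and reports the Robinson–Foulds distance to a
reference topology. A result is flagged low-support when the shortest
internal branch of the inferred tree is below 5% of the mean pairwise
distance, the signature of star-like data (measured: true star input
yields ratios ≤1.5%, resolved input ≥40%).

The region-class comparison uses a standard one-way ANOVA on pooled
pairwise identities per class; zero within-group variance with
differing means is reported as an infinite F with p = 0.

## The simulator

The generator's purpose is to make every analysis stage testable
offline with known ground truth, emulating the data model of real
grouper-type mitogenomes.

**Root assembly.** Genes follow the canonical 37-gene vertebrate order
with the usual strand assignments (ND6 plus eight tRNAs on the light
strand). Gene lengths are fixed values inside the observed ranges
(≈16.5 kb total). Start codons are ATG except COI (GTG) and ATP6
(CTG); ND2/COII/ND3/ND4/CYTB end in incomplete stops. The four real
overlaps are honoured exactly by constrained joint sampling of the
coupled gene ends: the downstream gene's head is pinned into the
upstream gene's tail (for ND5/ND6, across strands via reverse
complement), and free positions are rejection-sampled until both
reading frames are stop-free with correct terminal stops. Random bases
draw i.i.d. from heavy-strand equilibrium frequencies (default
A 0.29, T 0.27, G 0.16, C 0.28 — the C>G bias of real heavy strands);
light-strand genes draw their coding sense from the mirrored
frequencies, making asymmetry a strand property. Drawn stop codons in
CDS are repaired by redrawing a single base, a minimal intervention
that keeps marginal composition close to target. tRNAs are built from
a cloverleaf template (acceptor 7 bp, D-arm 4+8+4, anticodon arm 5+7+5
with the anticodon at loop positions 3–5, variable region, T-arm
5+7+5), with the D-arm replaced by a 4-base connector for
tRNA-Ser(AGY); candidates are rejected until the package's own
assessor recovers the intended architecture and anticodon. The control
region carries an ETAS tract (default six copies of a 40 bp unit
containing TACAT and ATGTA), the six CCD blocks and CSB-1..3 at known
offsets, padded to 900 bp (within the observed 721–1264); the O_L
spacer (38 nt, within 33–43) holds an 8 bp GC stem, T₆ loop, GCCGG at
the stem base and a pyrimidine 5' flank whose last base is fixed to T
so the flank cannot extend the designed stem.

**Evolution.** Sequences evolve down a supplied or random ultrametric
tree (depth 1, merge heights ≥0.05 apart) under per-class proposal
rates (defaults: rRNA 0.02, tRNA 0.025, CDS 0.06/0.12/0.24 for
slow/mid/fast classes — cytochrome oxidases slow, ND6 and ATP8 fast —
CR and spacers 0.15) with codon-position multipliers 1.0/0.4/1.6
(3rd > 1st > 2nd). Substitutions follow an F81 process: a site is hit
with probability 1 − exp(−rate·t/(1−Σπ²)) and redrawn from the
equilibrium frequencies. F81 is the composition-preserving extension
of Jukes–Cantor and reduces to it exactly under uniform frequencies
(which the JC-expectation tests use); plain JC would drift composition
toward uniformity and contradict the generator's own composition
targets. CDS mutations creating internal stops or touching start/stop
codons are rejected (both frames checked inside overlaps, which evolve
at the slower of the two genes' rates), and non-synonymous changes fix
with probability ω (default 0.35), so emitted clades show realistic
Ka/Ks < 1. Planted motifs (TAS/cTAS, the nine CSBs, the O_L element)
are held invariant — they are, after all, the conserved elements — and
the ETAS tract evolves concertedly: one unit sequence per genome is
evolved and copied to all repeats, emulating the slippage-driven
homogenization that keeps real tandem arrays uniform; without it,
within-genome copies would diverge at twice the root-to-tip distance
and the tract would stop being a detectable repeat.

**Duplication events.** Applied per taxon after evolution: tandem mode
copies the source gene immediately downstream and rewrites the copy's
anticodon (e.g. TAC→AAT converts a redundant tRNA-Val into a new
tRNA-Ile); CR mode inserts a strand-flipped copy at the CR midpoint.
All downstream coordinates shift consistently, and the truth object
records every event and planted offset.

**A separate selection-aware pair simulator** generates two coding
sequences from a common stop-free ancestor, accumulating uniform
substitution proposals (0.5 per site across the pair) that fix always
if synonymous and with probability ω otherwise; it underlies the Ka/Ks
recovery checks (estimated ω ≈ 0.25–0.30 for generating ω = 0.25 —
equal-pathway NG86 is known to sit slightly high under purifying
selection).

**What the simulator does not emulate.** No indels inside genes (so
per-gene alignments are trivial and alignment-quality effects on
identity are untested), no realistic codon substitution matrices
(GY94/MG94), no rate variation beyond the class/position structure, no
within-genome repeat-number variation, and tRNA secondary structure is
not conserved under evolution (arms mutate independently), so
cloverleaf assessments are guaranteed only for the built templates.
Passing tests therefore demonstrate correctness of the statistics and
detectors under the stated generative model, not robustness to every
artefact of real data.

**Determinism and composition targets.** A single NumPy RNG stream
keyed by the seed drives root assembly, tree generation, pre-order
branch evolution and event injection, in that order; output is
byte-identical across runs. Emitted-genome composition converges to
the configured equilibrium frequencies for unstructured sequence;
whole-genome skews sit within about 0.015 of the configured targets
because self-complementary stems (tRNA arms, the O_L hairpin, ~6% of
the genome) are inherently skew-neutral and fixed motifs carry their
own composition. The property tests bound the unstructured fraction at
three standard errors of the pooled sample and the whole genome at
±0.02.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: clades of 2–8 taxa of full-length (≈16.5 kb) genomes,
50-seed ω recovery at 500 codons, 20-seed rank recovery, and
three-seed structural recovery over four-taxon clades — sizes chosen so
the whole suite completes in a couple of minutes while keeping
Monte-Carlo assertions at ≥3σ margins. Full-scale replication of
published per-gene identities would require downloading the original
genome accessions and is deliberately out of scope here.

## Known limitations

- The CSB scanner is gapless; a block interrupted by an indel scores as
  mismatches and may fall below tolerance.
- The ETAS boundary is defined by CSB-F; control regions without a
  detectable CSB-F report an unbounded ETAS domain.
- The duplicate-tRNA classifier assumes the canonical complement as the
  baseline; genomes with lineage-specific losses would need an adjusted
  expected set.
- Identity denominators, alignment scoring and the Ka/Ks variant are
  package decisions where the field's published tables rarely state
  theirs; comparisons against published numbers should expect
  method-level scatter of a few percentage points.
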