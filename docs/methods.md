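# Methods

This note records the models, rules, parameter choices and numerical
conventions behind `drnamap`, and what the synthetic validation does and
does not demonstrate.

## Coordinates and strand handling

All internal coordinates are 0-based half-open on the forward reference
strand with the strand stored explicitly; point features (TSSs,
processing sites) store the genomic index of the +1 nucleotide. GFF3
import/export converts to/from 1-based inclusive; bedGraph is 0-based
half-open; text wiggle is 1-based. Minus-strand wiggle tracks in either
the negative-value or positive-value dialect are accepted and stored as
magnitudes.

Every strand-sensitive algorithm (TSS calling, clustering, terminator
scanning, transcript extension, window statistics) operates on the
reversed array or reverse-complemented sequence through the same
plus-strand code path. This makes strand-mirror symmetry hold by
construction, and it is verified end-to-end: reverse-complementing an
entire dataset reproduces every output table field-for-field after the
mirror transform. Window sums for coverage statistics are computed on
integer arrays so that means are exactly reproducible regardless of
summation order.

## TSS and processing-site detection

Detection operates on per-million-normalized 5'-end tracks, averaged over
replicates within a condition. The three gates (step height ≥ 0.3
per-million, step factor ≥ 2 against the strand-aware upstream neighbor,
TEX+/TEX− enrichment ≥ 2) and the 3 nt cluster width are the established
defaults for this class of detector; all are `PipelineParams` fields. The
denominator floor ε = 0.1 normalized counts bounds ratios when the
neighbor or the untreated library is empty. The first position of a
replicon in reading orientation has no upstream neighbor and is never a
step. Within a cluster, and when consolidating across conditions
(tolerance 3 nt), ties in signal break toward the 5'-most position so
output is deterministic. Processing sites use the identical step machinery
on the TEX− track with the enrichment gate inverted. Replicate handling is
mean-before-threshold; per-replicate calling was deliberately left out of
scope of the default path.

## TSS classification

The upstream window of a gene is the 300 positions ending at (and
including) the first base of the CDS, so a TSS at the start codon counts
as upstream with a 0 nt leader. Among window occupants on the gene's
strand, the highest step height wins primary; ties break toward the
nearest start and then toward the gene identifier (never toward genomic
left/right, which would break mirror symmetry). A TSS can be primary for
at most one gene: when it tops two genes' windows it is assigned to the
nearer start, the farther gene falls back to its best remaining occupant,
and — to keep the primary and secondary categories mutually exclusive at
the TSS level — the contested TSS takes no secondary label for the farther
gene. Internal is sense-within-gene-body; antisense is opposite-strand
within the body ± 100 nt; orphan is the absence of all other labels.
A literal brute-force enumerator of these rules doubles as a test oracle
(1000 random micro-configurations per run, exact agreement required).

## Intrinsic terminator scanning

The scanner is a transparent hairpin + U-tract search: perfect stems
(Watson–Crick plus G:U) of 4–20 bp, loops of 3–10 nt, hairpin score
`3·nGC + 2·nAU + 1·nGU − loop_length`, and ≥ 5 T (template sense) within
the 8 nt downstream of the stem. Overlapping hits resolve greedily to the
highest score (ties toward the 5'-most start, then geometry), which also
collapses the sub-stems of every maximal stem.

The score floor is the one deliberately calibrated default. An analytic
binomial estimate under an i.i.d. 43 % GC null showed that a floor of 8
admits on the order of 10² spurious hairpin+U-tract loci per 100 kb —
useless as 3'-boundary evidence. The floor was therefore calibrated on the
proper null for this statistic, dinucleotide-composition-preserving
(Altschul–Erickson) shuffles of the reference genome, scanning floors
16–20 over twenty shuffle realizations each: 19 is the smallest floor
whose spurious-call rate stays at or below two per 100 kb in every
realization (max 2, mean 0.4), while canonical terminators (≥ 7 bp
predominantly G:C stems, scoring ≥ 21) are recovered completely with a
2-point margin; 18 reaches 3 per 100 kb in the tail, and 20 would leave
only one score unit of recall margin. The default is 19; the scoring
arithmetic itself is exercised in tests at an explicit floor of 16 with
the classic 7 bp G:C-stem example.

Coverage confirmation uses fixed 50 nt windows on either side of the
hairpin (strand-aware, truncated and flagged at replicon edges):
supported ⇔ downstream/upstream mean ratio ≤ 0.5 and upstream mean ≥ 5
reads. Fixed windows keep the rule deterministic and testable; a
statistical change-point formulation was considered and rejected as
harder to validate.

## Transcripts, operons, UTRs, sORFs

5' UTR length is the strand-aware distance from a gene's primary TSS to
its start codon; `leaderless` is strict `< 10` nt and `long` strict
`> 100` nt, and UTR statistics are computed over primary TSSs only.
Transcripts extend 3' from each primary or orphan TSS while the mean raw
coverage over a sliding 25 nt window stays ≥ 5 reads, ending at the first
coverage-supported terminator inside the extension (at the stem's 3' edge
plus the 8 nt tail window) or at the falloff point; a TSS with no
downstream coverage yields a minimal transcript flagged low-expression.
Transcript and segment thresholds use raw read counts (the "minimum
average coverage 5" convention), not normalized units; the per-position
expression envelope is the max over conditions of the replicate-mean
untreated total coverage. Operons are the maximal same-strand gene runs
contained in one transcript, with runs strictly contained in a longer run
absorbed; covered single genes are monocistrons. The sORF scanner reports
ORFs of 10–100 codons starting ATG/GTG/TTG with an in-frame stop, applied
to long-UTR regions.

## RNA folding

The bundled reference backend is a dynamic program over nested structures
with pair energies G:C −3, A:U −2, G:U −1 kcal/mol, a minimum hairpin loop
of 3 nt, and a +4 kcal/mol penalty per hairpin loop. It is exact for that
model (verified against exhaustive enumeration up to n = 14) and
deliberately simple: the pipeline needs a reproducible structure-vs-no-
structure discriminant, not thermodynamic accuracy. The energy model is
not strand-symmetric in general — a G:U pair reverse-complements to the
unpairable A:C — so exact reverse-complement invariance holds (and is
tested) only over wobble-free alphabets. An external nearest-neighbor
engine (the `RNAfold` binary) can be swapped in via
`fold_energy(..., backend="vienna")` or any callable; tests use callable
backends to probe the filter boundary exactly and confirm that the
reference model orders structured vs unstructured sequences the same way
as the thermodynamic engine.

## sRNA discovery

Candidates come from two sources: maximal expressed runs (per-strand
coverage ≥ 5) that overlap no gene in sense orientation, and gene-anchored
intervals carved with primary TSSs, processing sites, terminators and
coverage drops (leader 5'-end → last processing site before the CDS;
3'-region site → parental transcript end; operon-gap site pairs). The
decision tree then re-checks every gate on the interval itself, in fixed
precedence: intergenic, cis-antisense, 5'-UTR-derived, 3'-UTR-derived,
intra-operonic; rejection carries the first failed gate (`length`,
`coverage`, `folding`, `overlaps_gene`, `no_tss`, `no_class`).

Two precedence refinements keep the classes disjoint where the bare rules
would overlap. First, the intergenic rule requires the 5'-end TSS not to
be any gene's *primary* TSS and the interval to lie outside operon spans —
a leader-derived RNA shares its mRNA's TSS and an operon-internal RNA
lives inside its operon, while a trans-encoded sRNA owns an orphan TSS.
Second, the 3'-UTR-derived rule requires the candidate to share its 3'
end (within 20 nt) with the parental transcript, which separates it from
intra-operonic RNAs that also start near a gene's 3' region but end at an
internal processing site. Association tolerances are declared parameters:
±5 nt for TSS/processing-site-to-end matching, 20 nt for terminator
sharing, last 50 nt of a CDS as its "3' region", and the 25 nt
window / 0.5 ratio drop convention shared with terminator confirmation.
"Minimum average coverage 5" is interpreted as the per-nucleotide mean
over the candidate on the expression envelope. High-confidence flagging
is restricted to intergenic candidates with a TSS and a terminator 3' edge
within 20 nt of the candidate end — always a subset of the intergenic
class, and checked exhaustively on every run. An optional user-supplied
exclusion list can stand in for homology pre-screens against external
databases, which are out of scope.

The duplex scanner is a pedagogical surrogate for accessibility-aware
interaction predictors: gapless antiparallel offsets, pair scores G:C 2 /
A:U 1 / G:U 0.5, a 2-point opening penalty per interior mismatch run,
terminal mismatches trimmed, and a reported hit requiring score ≥ 6 and a
contiguous ≥ 6 bp seed. It ignores intramolecular structure by design.

## Promoter scanning

Promoter coordinates place +1 at the TSS and −1 immediately upstream (no
zero); the scan window is −50..+1, extracted strand-aware and truncated
(flagged) at replicon edges. A box's center is its start offset plus
`(len−1)//2`. The default motif is the Bacteroidetes primary sigma-factor
promoter: box TAnnTTTG with centers allowed in −10..−4, box TTTG with
centers in −36..−30 (±3 around the canonical −7/−33 positions), one
mismatch allowed per box, spacer AT fraction ≥ 0.6. The best placement is
fewest total mismatches, then the most-upstream distal box; box-only
partial hits are reported when a spec allows them. The second promoter
motif described for this phylum is available only as a sequence logo, so
no default consensus string is fabricated for it — it is supplied by the
user (or by the synthetic generator for testing) as a `MotifSpec`.
Frequencies per TSS category count full hits only, with category sizes as
denominators.

## Expression summaries

rpkm is `count · 10⁹ / (library_size · length)`. Because the pipeline
ingests coverage tracks rather than alignments, a feature's "count" is
approximated as its summed per-base total coverage (mean coverage ×
length); this is documented as an approximation and affects all features
equally within a library. Condition values are replicate means.
Row-relative rendering divides each row by its mean (zero rows pass
through as zeros and are flagged). Pairwise condition ratios are reported
raw and labeled non-statistical; differential-expression testing is out
of scope.

## The synthetic data generator

The generator emulates the statistical structure the assay produces, with
defaults fixed at the validation study conditions: a 100 kb, 43 % GC
genome; 60 genes in six roles (5 plain with 5' UTRs of 9/10/100/101/32 nt
to pin the flag boundaries, 10 long-leader genes carrying 5'-UTR-derived
sRNAs, 10 genes with 3'-UTR-derived sRNAs, 10 two-gene operons with
intra-operonic sRNAs in their gaps, 10 antisense-sRNA hosts, 5 silent);
exactly 80 planted TSSs (35 primary, 5 secondary, 5 internal, 10
antisense = the cis-antisense sRNA starts, 25 orphan = 10 intergenic sRNA
+ 10 decoy + 5 standalone); 50 canonical terminators (9 bp stems with
7 G:C + 2 A:T pairs, 4 nt loops, U₈ tails, hairpin score 21); 40
processing sites; and two-box promoters embedded upstream of 81 % of
primary TSSs (60 % of secondary/orphan), with initiating nucleotides drawn
A 45 % / G 41 % / C 7 % / T 7 %.

Coverage is negative-binomial per position (variance m + α·m², α = 0.2
default; Poisson as α → 0): 5'-end peaks of mean 500 raw reads at library
size 10⁷ (50 per million) in TEX+ and 1/5 of that in TEX− at TSSs;
processing-site peaks on TEX− with the TEX+ side halved — the exonuclease
degrades 5'-monophosphate ends, so processed sites are depleted, not
enriched, in the treated library; sparse uniform 5'-end background (0.02
reads/nt); piecewise-constant transcript coverage (genes 20–60×, sRNAs
and decoys 50–150×, leaders of long-UTR genes boosted 3×) over background
0.5 reads/nt. Three conditions emulating growth phases with three
replicates each; every feature is expressed in all conditions with
probability 0.45, otherwise in a random proper subset, so cross-condition
consolidation is exercised. Structured sRNA bodies are built from 8 bp
mixed G:C/A:U stems joined by T-free A/C linkers (so no spurious U-tract
follows a body stem); decoys are drawn from the A/C alphabet, in which no
Watson–Crick or wobble pair exists at all, guaranteeing zero folding
energy.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: read-level artifacts (mapping ambiguity,
ligation and PCR bias, 3'-end coverage decay), partial TEX digestion
efficiency gradients, overlapping and nested transcription units,
condition-dependent processing, and real promoter/terminator sequence
diversity. Recovery rates near 1.0 on this generator demonstrate
correctness of the rules under their own assumptions, not expected field
performance on biological libraries.

## Validation design and problem sizes

The standard validation run uses the default 100 kb dataset (completing
in a few seconds per stage and well under five minutes end-to-end on one
CPU), 1000 random micro-configurations for the classification oracle,
single dinucleotide-shuffled genomes for terminator specificity, and a
30 kb dataset for the full strand-mirror comparison. The acceptance
script (`scripts/acceptance.py`) recomputes all headline quantities from
scratch from a single seed; every reported number is produced by running
the pipeline, never stored.

## Known limitations

Circular replicons are handled linearly: features wrapping the origin are
not supported and wrapping input is an error. Manual curation of TSS
calls, homology-based sRNA pre-screens, conservation analysis, riboswitch
annotation, CRISPR detection and differential-expression statistics are
out of scope. The terminator scanner requires perfect stems (no internal
mismatches or bulges), trading sensitivity to imperfect hairpins for
specificity and transparency. The folding model's absolute energies are
not thermodynamic quantities and should only be compared against the
model's own threshold.
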