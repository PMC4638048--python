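# Methods

This note documents the models, conventions and design choices behind
`pitkit`, in the order the pipeline runs. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates

All internal coordinates are 0-based half-open, on the **forward** strand of
whatever sequence they index (transcript or genome). Conversion to the
1-based inclusive convention happens only in the GFF3/SAM serializers. This
single-convention rule is the main defence against off-by-one drift in the
projection arithmetic.

A spliced alignment is a list of exon blocks `(t_start, t_end, g_start,
g_end)` sorted by transcript coordinate, so transcript intervals are
contiguous and tile `[0, aligned_length)`. On strand `+` genome intervals
ascend along the list; on strand `-` they descend, and within each block a
rising transcript coordinate maps to a falling genome coordinate — i.e.
transcript position 0 sits in the block with the largest genome coordinate.
(Transcript-sorted and genome-sorted orderings cannot both hold on the
reverse strand; transcript order was chosen because projection iterates in
transcript space.)

## Six-frame ORF finding

Frames +1/+2/+3 read the forward transcript at codon offsets 0/1/2; −1/−2/−3
read the reverse complement the same way. Candidate ORFs are maximal
stop-free codon runs. The keep rules are controlled by four parameters:

| parameter | default | rationale |
|---|---|---|
| `min_aa` | 20 | shortest protein likely to yield a detectable tryptic peptide |
| `mode` | `per-frame-longest` | at most one ORF per frame; `all-above-min` keeps every candidate |
| `require_start` | `False` | de novo transcripts are frequently 5'-truncated fragments; demanding ATG would discard real protein ends |
| `allow_partial` | `True` | runs open at a transcript end (no bounding stop) still count |

Ties for per-frame-longest go to the smaller forward-strand start
(determinism). Codons containing `N` translate to `X` and do **not**
terminate a run — assembler ambiguity should not shatter ORFs — but
candidates that are more than 50 % `X` are dropped as junk. Reverse-frame
coordinates are reported after reflection to the forward strand, so
`nt_end − nt_start = 3 × len(protein)` always, and frame sign alone records
the translation strand. Whether one-per-frame or all-above-threshold better
matches historical ORF finders is not decidable from available descriptions;
both modes are first-class and the exhaustive-enumeration oracle in the test
suite covers both.

Translation uses the standard genetic code (Biopython's table 1) with the
`N → X` rule layered on top, because a resolvable ambiguous codon (e.g.
`GGN`) would otherwise translate silently while this toolkit prefers to mark
any ambiguity.

## Decoys, peptide-level FDR, filtering

Decoys are full-sequence reversals with a `DECOY_` id prefix: reversal
preserves length and composition (verified by histogram-equality tests), and
the prefix makes decoy detection string-exact. Peptides are keyed by
sequence **plus** modification string for FDR purposes; a peptide matching
both a target and a decoy protein counts as target. Ranking best score
first, with score ties placing decoys first (the conservative order), the
FDR estimate at rank *r* is `D/max(T,1)` and the q-value is the running
minimum from the worst rank upward, capped at 1. The simple `D/T` estimator
is the default; `2D/(T+D)` is available via `estimator="concatenated"`.
Filtering keeps targets with `q ≤ threshold` (default 0.01).

The threshold semantics ("remove peptides below a threshold") could in
principle mean a score cut; it is implemented as an FDR cut because the
evaluation convention this toolkit reproduces fixes a 1 % *peptide-level
FDR* threshold.

## Peptide mapping and ambiguity grouping

Mapping is exact substring search of each retained plain sequence against
every **target** protein, reporting all occurrences; unmapped peptides are
returned as diagnostics, never dropped. Isoleucine and leucine are distinct
by default (`equate_il` flag to merge them) — distinctness is the
conservative choice when the mass-spectrometric indistinguishability of I/L
has already been resolved upstream by the search engine.

Grouping visits proteins by (distinct peptide count descending, accession
ascending). A protein equal in peptide set to an existing anchor joins as a
same-set member; a proper subset joins the **first** group in creation order
whose anchor set contains it; otherwise it founds a group. Anchors therefore
have maximal evidence and alphabetical priority on ties. Finally groups
whose anchor has fewer than `min_peptides` (default 2) distinct peptides are
discarded; the count uses distinct plain sequences by default
(`count_plain_sequences=False` counts modified keys instead). The
first-group rule for multi-subset attachment keeps the procedure
deterministic and permutation-invariant (property-tested).

## Genome projection

A peptide at protein offsets `[p0, p1)` of an ORF becomes the transcript
interval `[nt_start + 3·p0, nt_start + 3·p1)` for forward frames; for
reverse frames, protein index 0 sits at the ORF's forward-strand **end**, so
the interval is `[nt_end − 3·p1, nt_end − 3·p0)`. The interval is then
intersected with the alignment blocks; junction-spanning peptides yield
multiple genome segments, ordered by genome coordinate. The feature strand
is the alignment strand flipped when the ORF frame is negative.

Peptide features are emitted in nucleotide space (CDS-like) because genome
browsers consume nucleotide-coordinate GFF3. Multi-segment peptides use the
GFF3 shared-ID multi-line convention (simplest form browsers round-trip);
GFF3 phase is populated per segment so that, walking segments in translation
order, each phase gives the bases to skip to the next codon boundary. SAM
records use `M` runs for segments and `N` runs for inter-segment gaps;
reverse-strand records set flag 16 and carry the forward-genome-strand bases
as SEQ, per SAM convention. ORFs whose transcript lacks an alignment, or
peptides escaping the aligned region, are tallied in the run report —
never silently dropped.

The standing correctness check is the round-trip oracle: extracting each
feature's genome segments in order, reverse-complementing on strand `-`,
and translating must reproduce the peptide exactly. This is asserted for
100 % of features on every synthetic scene the suite generates.

## Cross-search comparison

Peptide overlap uses **plain** sequences (exact sequence matches across
searches; modifications are search-engine-specific bookkeeping) and is
reported as `100·shared/union`, rounded to nearest — the only definition
arithmetically consistent with the published totals the acceptance script
recomputes. Database-absence attribution percentages are **truncated** to
one decimal, matching the printed convention of all four published values
(one of which is inconsistent with round-to-nearest).

The in-silico digest is fully tryptic — cleave after K/R except before P —
via `pyteomics.parser.cleave`, with missed-cleavage cap 2 and length window
7–45 by default. These knobs are exposed because production search engines
apply their own (unreproducible) missed-cleavage logic.

PAG matching accepts a hit only when `evalue < 1e-30` **strictly**
(boundary equality does not match). Matching is greedy, each PAG usable
once: pass 1 anchor↔anchor, pass 2 anchor↔member, candidates ordered by
ascending e-value with ties on the normalized accession pair — chosen for
determinism and label-swap symmetry, and validated against a brute-force
one-use matcher on small instances. Unmatched PAGs are triaged by a
first-hit-wins cascade (isoform of a matched group → no transcript evidence,
split into assembler-failure when a transcript was expected → ORF-finding
failure → single-peptide in the other search → extended ORF → no known
homology); any category whose auxiliary evidence is unavailable is disabled
and recorded, never guessed.

## Synthetic scenes: what they emulate, what they do not

`synthfix` generates, from one seed, a single-chromosome genome of ~50
spliced genes (2–5 exons of ≥30 nt, introns 80–400 nt, intergenic spacers
100–300 nt, half the genes on the reverse strand), each carrying one planted
protein-coding ORF of 80–250 residues delimited by an in-frame upstream stop
and a terminal stop, so the default ORF finder must recover it exactly
(the planted run is always the longest in its frame because UTRs are too
short to beat an 80-codon floor). Transcripts are exact spliced extracts;
ground-truth peptide segments come from an explicit per-base position map,
independent of the projection module they test.

PSM scores are two Gaussians — true matches N(25, 5), false/decoy matches
N(10, 5), a 3σ separation that retains most true peptides at 1 % FDR while
leaving a measurable false tail. A planted fraction (default 10 %) of
target PSMs draws from the false distribution, with an equal number of
decoy PSMs, which is the regime in which the `D/T` estimator is calibrated.

What passing these tests shows: coordinate arithmetic, strand handling,
FDR-estimator calibration under its own assumptions, and bookkeeping
(conservation of evidence) are correct. What it does not show: behaviour
under real spectra (score distributions are not Gaussian and engine scores
correlate with peptide properties), sequencing/assembly error (transcripts
here match the genome perfectly), chimeric or overlapping gene models, and
alignment error — real GMAP output can truncate or mis-splice, which the
unprojectable-item reporting handles but the generator does not emulate.

## Problem sizes

The test suite runs the ORF oracle on 100 random transcripts up to 3 kb,
the FDR calibration on 20 independent simulations of 10,000 PSMs over a
50-gene scene, grouping against an oracle on all ≤3-protein × ≤3-peptide
instances (exhaustive) plus 3,000 random ≤6×6 instances, and the projection
round trip on full 50-gene scenes — sizes at which every oracle is exact
and the whole suite completes in well under a minute on one CPU. The
acceptance script uses a 50-gene scene with 10 independent 10,000-PSM
simulations.
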