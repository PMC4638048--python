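# pitkit

A toolkit for **proteomics informed by transcriptomics (PIT)** — identifying
peptides and proteins by searching tandem-MS spectra against a protein
database built from the *same sample's* assembled transcripts, instead of a
reference proteome. This matters for non-model organisms with no (or poor)
reference annotation, for host–pathogen samples containing proteins from
several species, and for finding translated regions a curated proteome
misses.

`pitkit` implements the bespoke computational stages of that workflow; it
deliberately does **not** run the heavyweight external tools (read assembly,
spectrum search, spliced alignment, BLAST) — it builds their inputs and
consumes their outputs:

1. **Six-frame ORF database construction** (`orffinder`) — for each
   transcript, find open reading frames (maximal stop-free codon runs) in
   all six reading frames and emit the longest per frame (or all above a
   length floor) as a protein FASTA plus a provenance index.
2. **Identification post-processing** (`identpost`) — reversed-decoy
   database generation, collapse of peptide-spectrum matches (PSMs) to
   best-evidence peptides, peptide-level *q*-values by target–decoy
   counting, FDR filtering, exact-substring peptide-to-protein mapping, and
   **protein ambiguity groups** (PAGs): proteins sharing a peptide-evidence
   set, represented by the anchor protein with the most evidence (ties
   broken alphabetically), with a two-peptide retention rule.
3. **Genome integration** (`genomeintegrate`) — projection of identified
   ORFs and peptides through spliced transcript-to-genome alignments
   (GMAP-style GFF3/GTF exon features) into GFF3, SAM and tabular genome
   annotation, splitting junction-spanning peptides into multiple segments.
4. **Cross-search comparison** (`searchcompare`) — exact peptide-sequence
   overlap between two searches, attribution of search-specific peptides to
   absence from the opposing database's in-silico tryptic universe,
   homology-thresholded PAG matching (e-value strictly below 1e-30,
   anchor–anchor first, then anchor–submember, each PAG used once), and
   triage of unmatched PAGs into explanatory categories.
5. **Synthetic fixtures** (`synthfix`) — a seeded generator of genomes,
   spliced gene models, transcripts, planted ORFs and scored target/decoy
   PSMs with full ground truth, so the whole pipeline is testable offline.
6. **Format I/O** (`formats_io`) — strict readers/writers for FASTA, PSM
   TSV, BLAST tabular (outfmt 6), GFF3/GTF and SAM, plus a minimal
   mzIdentML 1.1 reader.

## The statistics in brief

*Peptide-level FDR.* PSMs are searched against targets plus reversed decoys.
Peptides (sequence + modifications) keep their best PSM score; ranking all
peptides best-first, the FDR estimate at rank *r* is `D(r) / max(T(r), 1)`
(decoy/target counts at rank ≤ *r*; a concatenated-style `2D/(T+D)`
estimator is available behind a flag), and the *q*-value is the minimum
estimate at this or any worse rank. Identification lists are filtered at
*q* ≤ 0.01 by default.

*Overlap accounting.* For two searches with retained plain-sequence sets A
and B, the reported overlap is `100·|A∩B| / |A∪B|`, rounded to the nearest
integer. A peptide unique to one search is attributed to *database absence*
when it does not occur in the fully tryptic digest (K/R cleavage, KP/RP
suppressed, ≤2 missed cleavages, length 7–45 by default) of the opposing
database.

## Worked example

Everything below runs from nothing — the first command fabricates the
"experiment" (a 20-gene genome, spliced transcripts, and 1,500 scored
target/decoy PSMs with 10 % planted false matches):

```
$ pit simulate --seed 42 --genes 20 --psms 1500 --out scene
$ pit orfs --transcripts scene/transcripts.fa --out orfs.fa --index orfs.tsv
120 ORFs from 20 transcripts
$ pit decoy --in orfs.fa --out orfs_td.fa
120 targets + 120 decoys
$ pit fdr --psms scene/psms.tsv --threshold 0.01 --out peptides.tsv
1650 PSMs -> 894 peptides (144 decoy) -> 606 retained at q<=0.01
$ pit group --peptides peptides.tsv --db orfs_td.fa --min-peptides 2 --out pags.tsv
606 peptides -> 606 evidences -> 20 PAGs
$ pit integrate --pags pags.tsv --peptides peptides.tsv --orf-index orfs.tsv \
    --alignments scene/alignments.gff3 --genome scene/genome.fa \
    --gff3 out.gff3 --sam out.sam --table out.tsv
integrated: mRNA=20, CDS=20, peptide_occurrences=601, unprojectable=0
```

Reading the numbers: 1,650 spectra collapse to 894 distinct peptides, of
which 144 are decoys; at the 1 % peptide-FDR threshold 606 target peptides
survive, map onto the ORF database, and group into 20 ambiguity groups (one
per simulated gene — the generator plants one protein-coding ORF per gene).
601 peptide occurrences project cleanly onto the genome; the 5 remaining
peptides belong to ORFs dropped by the two-peptide rule and are reported,
not silently lost. The GFF3 output is browser-ready, with junction-spanning
peptides as multi-line features sharing one ID:

```
##gff-version 3
chr1  pitkit  mRNA     10993  11771  .  +  .  ID=tr0010;Name=tr0010
chr1  pitkit  exon     10993  11117  .  +  .  ID=tr0010.exon1;Parent=tr0010
...
chr1  pitkit  peptide  11253  11273  0  +  0  ID=tr0010|F+3|2.pep1;Parent=tr0010|F+3|2;Name=SMAHQFR
```

The same features are written as SAM records (`M` runs for coding segments,
`N` runs for the introns between them) and as a flat table. Two searches are
compared with `pit compare --peptides-a … --peptides-b … --report report.tsv`,
optionally with `--pags-a/--pags-b/--blast` for PAG-level matching.

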