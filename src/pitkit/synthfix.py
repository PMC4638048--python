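"""Deterministic synthetic fixtures: genomes, spliced genes, transcripts,
planted ORFs, tryptic peptides and scored target/decoy PSMs with ground truth.

The generator emulates the statistical shape of a transcriptome-derived
search: each gene carries one planted protein-coding ORF (an ATG-initiated,
stop-terminated codon run, delimited upstream by an in-frame stop so the ORF
finder must recover it exactly), transcripts are exact spliced extracts of
the genome on either strand, and peptide-spectrum matches draw correct
identifications from the planted proteins' tryptic peptides and incorrect
ones from the wider target/decoy digest with a lower score distribution.
All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    BlastHit,
    FastaRecord,
    Gff3Feature,
    PsmRecord,
    TranscriptGenomeAlignment,
    write_blast_tabular,
    write_fasta,
    write_gff3,
    write_psm_table,
)
from .identpost import DECOY_PREFIX, ProteinAmbiguityGroup
from .orffinder import Transcript
from .searchcompare import TRIAGE_CATEGORIES, TriageEvidence, tryptic_digest

__all__ = [
    "SimParams",
    "GroundTruth",
    "Scene",
    "simulate_scene",
    "write_scene",
    "simulate_psms",
    "simulate_homology",
    "plant_triage",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic scene.

    Gene architecture (exon/intron/UTR lengths, ~50 genes over one
    chromosome) is sized like a compact eukaryotic locus set; the score
    model is two Gaussians with a 3-sigma gap, separated enough that a 1%
    FDR threshold retains most true peptides yet admits a measurable false
    tail.  ``frac_false_targets`` is the planted fraction of target PSMs
    drawn from the false-score distribution; an equal number of decoy PSMs
    is generated so the target-decoy estimator sees matched false evidence.
    """

    seed: int = 42
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    intron_len: tuple[int, int] = (80, 400)
    intergenic_len: tuple[int, int] = (100, 300)
    utr5_len: tuple[int, int] = (12, 60)
    utr3_len: tuple[int, int] = (20, 80)
    coding_aa: tuple[int, int] = (80, 250)
    min_exon_len: int = 30
    frac_reverse_strand: float = 0.5
    n_true_peptides_per_orf: int = 3
    n_psms: int = 2000
    score_true: tuple[float, float] = (25.0, 5.0)
    score_false: tuple[float, float] = (10.0, 5.0)
    frac_false_targets: float = 0.10
    planted_triage_counts: dict | None = None

    def validate(self) -> None:
        for name in ("exons_per_gene", "intron_len", "intergenic_len",
                     "utr5_len", "utr3_len", "coding_aa"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo}..{hi} is not positive ascending")
        for name in ("frac_reverse_strand", "frac_false_targets"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coding_aa[0] < 30:
            raise ValueError("coding_aa floor below 30 residues cannot guarantee "
                             "per-frame-longest recovery of planted ORFs")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-transcript blocks, planted ORF
    coordinates, per-peptide genome segments, per-PSM correctness labels."""

    transcripts: dict = field(default_factory=dict)  # tid -> {seqid, strand, blocks, sequence}
    orfs: dict = field(default_factory=dict)  # tid -> {nt_start, nt_end, aa}
    peptides: list = field(default_factory=list)  # {peptide, tid, strand, seqid, segments}
    psm_labels: dict = field(default_factory=dict)  # spectrum_id -> true|false_target|decoy


@dataclass
class Scene:
    genome: dict  # seqid -> sequence
    transcripts: list  # list[Transcript]
    alignments: list  # list[TranscriptGenomeAlignment]
    truth: GroundTruth


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _cut_points(rng: np.random.Generator, length: int, pieces: int, min_piece: int) -> list[int]:
    """Split [0, length) into `pieces` contiguous pieces each >= min_piece."""
    slack = length - pieces * min_piece
    if slack < 0:
        pieces = max(1, length // min_piece)
        slack = length - pieces * min_piece
    bounds = sorted(rng.integers(0, slack + 1, size=pieces - 1).tolist())
    sizes = []
    prev = 0
    for b in [*bounds, slack]:
        sizes.append(min_piece + b - prev)
        prev = b
    return sizes


def simulate_scene(params: SimParams | None = None) -> Scene:
    """Generate a genome with spliced genes and matching transcripts.

    Each transcript is an exact spliced extract of the genome; its planted
    ORF is the unique long stop-free run in its frame, so default ORF
    finding recovers it.  Ground-truth peptide segments are computed from a
    direct per-base transcript-to-genome position map, independently of the
    projection module.
    """
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    chrom_parts: list[str] = []
    offset = 0
    seqid = "chr1"
    truth = GroundTruth()
    transcripts: list[Transcript] = []
    alignments: list[TranscriptGenomeAlignment] = []

    for gi in range(params.n_genes):
        tid = f"tr{gi + 1:04d}"
        coding_n = int(rng.integers(params.coding_aa[0], params.coding_aa[1] + 1))
        coding_codons = rng.choice(_SENSE_CODONS, size=coding_n - 1)
        stop = _STOPS[int(rng.integers(0, 3))]
        utr5 = _random_nt(rng, int(rng.integers(*params.utr5_len))) + "TAA"
        utr3 = _random_nt(rng, int(rng.integers(*params.utr3_len)))
        coding = "ATG" + "".join(coding_codons)
        tseq = utr5 + coding + stop + utr3
        nt_start = len(utr5)
        nt_end = nt_start + len(coding)
        aa = "M" + "".join(
            _translate_codon(c) for c in coding_codons
        )

        # split into exons and lay out on the genome
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        sizes = _cut_points(rng, len(tseq), n_exons, params.min_exon_len)
        pieces = []
        t_off = 0
        for sz in sizes:
            pieces.append((t_off, t_off + sz, tseq[t_off:t_off + sz]))
            t_off += sz

        strand = "-" if rng.random() < params.frac_reverse_strand else "+"
        chrom_parts.append(_random_nt(rng, int(rng.integers(*params.intergenic_len))))
        offset += len(chrom_parts[-1])

        blocks: list[tuple[int, int, int, int]] = []
        if strand == "+":
            for i, (ts, te, seg) in enumerate(pieces):
                blocks.append((ts, te, offset, offset + len(seg)))
                chrom_parts.append(seg)
                offset += len(seg)
                if i < len(pieces) - 1:
                    intron = _random_nt(rng, int(rng.integers(*params.intron_len)))
                    chrom_parts.append(intron)
                    offset += len(intron)
        else:
            genome_order = pieces[::-1]  # transcript 3' end leftmost on genome
            placed: dict[int, tuple[int, int]] = {}
            for i, (ts, te, seg) in enumerate(genome_order):
                placed[ts] = (offset, offset + len(seg))
                chrom_parts.append(_revcomp(seg))
                offset += len(seg)
                if i < len(genome_order) - 1:
                    intron = _random_nt(rng, int(rng.integers(*params.intron_len)))
                    chrom_parts.append(intron)
                    offset += len(intron)
            for ts, te, seg in pieces:
                gs, ge = placed[ts]
                blocks.append((ts, te, gs, ge))

        aln = TranscriptGenomeAlignment(tid, seqid, strand, blocks)
        aln.validate()
        transcripts.append(Transcript(tid, tseq))
        alignments.append(aln)
        truth.transcripts[tid] = {
            "seqid": seqid, "strand": strand, "blocks": blocks, "sequence": tseq,
        }
        truth.orfs[tid] = {"nt_start": nt_start, "nt_end": nt_end, "aa": aa}

        # ground-truth peptide segments via an explicit per-base position map
        pos_map: list[int] = []
        for ts, te, gs, ge in blocks:
            if strand == "+":
                pos_map.extend(range(gs, ge))
            else:
                pos_map.extend(range(ge - 1, gs - 1, -1))
        digest = sorted(tryptic_digest(aa))
        picks = digest if len(digest) <= params.n_true_peptides_per_orf else [
            digest[int(i)] for i in rng.choice(len(digest),
                                               size=params.n_true_peptides_per_orf,
                                               replace=False)
        ]
        for pep in picks:
            p0 = aa.find(pep)
            t0, t1 = nt_start + 3 * p0, nt_start + 3 * (p0 + len(pep))
            positions = sorted(pos_map[t0:t1])
            segments = _runs(positions)
            truth.peptides.append(
                {"peptide": pep, "tid": tid, "seqid": seqid, "strand": strand,
                 "segments": segments}
            )

    chrom_parts.append(_random_nt(rng, int(rng.integers(*params.intergenic_len))))
    genome = {seqid: "".join(chrom_parts)}
    return Scene(genome, transcripts, alignments, truth)


def _translate_codon(codon: str) -> str:
    from .orffinder import translate

    return translate(codon)


def _revcomp(seq: str) -> str:
    from .orffinder import reverse_complement

    return reverse_complement(seq)


def _runs(sorted_positions: list[int]) -> list[tuple[int, int]]:
    segments: list[tuple[int, int]] = []
    start = prev = sorted_positions[0]
    for p in sorted_positions[1:]:
        if p != prev + 1:
            segments.append((start, prev + 1))
            start = p
        prev = p
    segments.append((start, prev + 1))
    return segments


# --------------------------------------------------------------------------
# PSM simulation
# --------------------------------------------------------------------------

def simulate_psms(orf_db_with_decoys, params: SimParams,
                  true_proteins=None, seed: int | None = None):
    """Simulate scored PSMs against a target+decoy database.

    Correct PSMs sample tryptic peptides of the true proteins (default: all
    targets) with scores from the "true" Gaussian; false target PSMs and all
    decoy PSMs sample peptides of the target/decoy digests with scores from
    the "false" Gaussian.  Returns ``(psms, labels)`` where labels maps
    spectrum id to ``true``/``false_target``/``decoy``.
    """
    records = list(orf_db_with_decoys)
    if not records:
        raise ValueError("empty database")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    targets = [r for r in records if not r.id.startswith(DECOY_PREFIX)]
    decoys = [r for r in records if r.id.startswith(DECOY_PREFIX)]
    if not targets or not decoys:
        raise ValueError("database must contain both targets and decoys")

    def universe(recs):
        pep2prot: dict[str, list[str]] = {}
        for rec in recs:
            for pep in tryptic_digest(rec.sequence):
                pep2prot.setdefault(pep, []).append(rec.id)
        return pep2prot

    target_univ = universe(targets)
    decoy_univ = universe(decoys)
    if true_proteins is None:
        true_pool = sorted(target_univ)
    else:
        true_pool = sorted(set().union(*(tryptic_digest(s) for s in true_proteins))
                           & set(target_univ))
    target_pool = sorted(target_univ)
    decoy_pool = sorted(decoy_univ)
    if not true_pool:
        raise ValueError("no tryptic peptides available from the true proteins")

    n_false = round(params.frac_false_targets * params.n_psms)
    n_true = params.n_psms - n_false
    n_decoy = n_false

    psms: list[PsmRecord] = []
    labels: dict[str, str] = {}
    spec = 0

    def emit(pool, univ, n, mean_sd, label):
        nonlocal spec
        idx = rng.integers(0, len(pool), size=n)
        scores = rng.normal(mean_sd[0], mean_sd[1], size=n)
        for i, s in zip(idx, scores):
            pep = pool[int(i)]
            sid = f"spec_{spec:06d}"
            spec += 1
            hints = univ.get(pep, [])
            psms.append(PsmRecord(sid, pep, float(s), protein_hint=";".join(hints)))
            labels[sid] = label

    emit(true_pool, target_univ, n_true, params.score_true, "true")
    emit(target_pool, target_univ, n_false, params.score_false, "false_target")
    emit(decoy_pool, decoy_univ, n_decoy, params.score_false, "decoy")
    return psms, labels


# --------------------------------------------------------------------------
# homology simulation
# --------------------------------------------------------------------------

def simulate_homology(pags_a, pags_b, seed: int = 0, frac_ambiguous: float = 0.0,
                      n_background: int = 20):
    """Generate BLAST-tabular hits pairing PAG anchors across two lists.

    The i-th PAG of each list is truth-paired (anchor to anchor) with an
    e-value sampled strictly below 1e-30; background hits between unpaired
    accessions sit above the threshold; a ``frac_ambiguous`` fraction of the
    truth pairs receive an extra below-threshold hit to a second PAG.
    Returns ``(hits, truth_pairs)`` with truth pairs as (pag_id_a, pag_id_b).
    """
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    truth_pairs: list[tuple[str, str]] = []

    def mk(q, s, evalue):
        return BlastHit(q, s, 95.0, 100, 5, 0, 1, 100, 1, 100, evalue, 200.0)

    n_pairs = min(len(pags_a), len(pags_b))
    for i in range(n_pairs):
        pa, pb = pags_a[i], pags_b[i]
        evalue = 10.0 ** -float(rng.uniform(31, 60))
        hits.append(mk(pa.anchor_id, pb.anchor_id, evalue))
        truth_pairs.append((pa.pag_id, pb.pag_id))
        if frac_ambiguous > 0 and rng.random() < frac_ambiguous and n_pairs > 1:
            j = int(rng.integers(0, n_pairs))
            if j != i:
                hits.append(mk(pa.anchor_id, pags_b[j].anchor_id,
                               10.0 ** -float(rng.uniform(31, 45))))
    for _ in range(n_background):
        pa = pags_a[int(rng.integers(0, len(pags_a)))]
        pb = pags_b[int(rng.integers(0, len(pags_b)))]
        hits.append(mk(pa.anchor_id, pb.anchor_id, 10.0 ** -float(rng.uniform(2, 29))))
    order = rng.permutation(len(hits))
    return [hits[int(i)] for i in order], truth_pairs


# --------------------------------------------------------------------------
# triage planting
# --------------------------------------------------------------------------

def plant_triage(counts: dict[str, int], seed: int = 0):
    """Construct unmatched PAGs and evidence that trigger known categories.

    ``counts`` maps category name -> how many PAGs should land there.
    Returns ``(unmatched_pags, evidence, truth)`` with truth mapping pag_id
    to its planted category.
    """
    unknown = set(counts) - set(TRIAGE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown triage categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pags: list[ProteinAmbiguityGroup] = []
    truth: dict[str, str] = {}
    ev = TriageEvidence(
        matched_accessions=set(),
        has_transcript={},
        assembly_expected={},
        orf_survives={},
        other_search_peptide_count={},
        orf_extends_reference={},
    )
    n = 0
    for category, count in counts.items():
        for _ in range(count):
            n += 1
            acc = f"P{n:04d}"
            pag = ProteinAmbiguityGroup(
                pag_id=f"UPAG_{n:04d}", anchor_id=acc,
                peptide_keys=frozenset({f"PEP{n}A", f"PEP{n}B"}),
            )
            ev.has_transcript[acc] = True
            ev.assembly_expected[acc] = False
            ev.orf_survives[acc] = True
            ev.other_search_peptide_count[acc] = 0
            ev.orf_extends_reference[acc] = False
            if category == "isoform_of_matched":
                iso = f"{acc}-iso"
                pag.same_set_members.append(iso)
                ev.matched_accessions.add(iso)
            elif category == "no_transcript_evidence":
                ev.has_transcript[acc] = False
            elif category == "assembly_failure":
                ev.has_transcript[acc] = False
                ev.assembly_expected[acc] = True
            elif category == "orf_failure":
                ev.orf_survives[acc] = False
            elif category == "single_peptide_in_other_search":
                ev.other_search_peptide_count[acc] = 1
            elif category == "extended_orf":
                ev.other_search_peptide_count[acc] = 2
                ev.orf_extends_reference[acc] = True
            truth[pag.pag_id] = category
            pags.append(pag)
    order = rng.permutation(len(pags))
    pags = [pags[int(i)] for i in order]
    return pags, ev, truth


# --------------------------------------------------------------------------
# scene serialization
# --------------------------------------------------------------------------

def write_scene(scene: Scene, out_dir, psms=None) -> dict:
    """Write a scene to plain-text files; returns the path map.

    Emits genome.fa, transcripts.fa, alignments.gff3, truth.json and, when
    PSMs are supplied, psms.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.fa",
        "alignments": out / "alignments.gff3",
        "truth": out / "truth.json",
    }
    write_fasta([FastaRecord(k, "synthetic genome", v) for k, v in scene.genome.items()],
                paths["genome"])
    write_fasta([FastaRecord(t.id, "synthetic transcript", t.sequence)
                 for t in scene.transcripts], paths["transcripts"])

    features: list[Gff3Feature] = []
    for aln in scene.alignments:
        g_lo = min(b[2] for b in aln.blocks)
        g_hi = max(b[3] for b in aln.blocks)
        features.append(
            Gff3Feature(aln.seqid, "synthfix", "mRNA", g_lo + 1, g_hi, None,
                        aln.strand, ".", {"ID": aln.transcript_id})
        )
        for i, (_, _, gs, ge) in enumerate(sorted(aln.blocks, key=lambda b: b[2]), 1):
            features.append(
                Gff3Feature(aln.seqid, "synthfix", "exon", gs + 1, ge, None,
                            aln.strand, ".",
                            {"ID": f"{aln.transcript_id}.e{i}", "Parent": aln.transcript_id})
            )
    write_gff3(features, paths["alignments"])

    truth_doc = {
        "transcripts": {
            tid: {k: v for k, v in info.items() if k != "sequence"}
            for tid, info in scene.truth.transcripts.items()
        },
        "orfs": scene.truth.orfs,
        "peptides": scene.truth.peptides,
        "psm_labels": scene.truth.psm_labels,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, default=list)

    if psms is not None:
        paths["psms"] = out / "psms.tsv"
        write_psm_table(psms, paths["psms"])
    return paths
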