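"""Projection of identified ORFs and peptides onto genome coordinates.

A spliced transcript-to-genome alignment (exon blocks) lets any transcript
interval be mapped into genome space; peptides identified against a
transcript-derived ORF database become genome features this way, possibly
split across splice junctions.  The results are emitted as a GFF3 hierarchy
(mRNA -> exon, CDS, peptide), as SAM records (M runs for segments, N runs
for the introns between them) and as a flat table.

All arithmetic is done in 0-based half-open coordinates; 1-based inclusive
conversion happens in the writers from :mod:`pitkit.formats_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import Gff3Feature, TranscriptGenomeAlignment, write_gff3, write_sam
from .identpost import PeptideEvidence
from .orffinder import reverse_complement

__all__ = [
    "GenomicPeptideFeature",
    "ProjectionError",
    "project_interval",
    "project_peptide",
    "to_cigar",
    "integrate",
    "IntegrationResult",
]


class ProjectionError(ValueError):
    """An interval fell outside the aligned region of its transcript."""


@dataclass(frozen=True)
class GenomicPeptideFeature:
    """A peptide's genome-space segments, ready for GFF3/SAM emission.

    ``segments`` are 0-based half-open genome intervals ordered by genome
    coordinate; ``frame_phase`` carries the GFF3 phase of each segment in
    the same order.  ``strand`` is the coding strand on the genome: the
    alignment strand flipped when the peptide's ORF lies on a reverse
    reading frame of the transcript.
    """

    peptide_key: str
    plain_sequence: str
    orf_id: str
    transcript_id: str
    seqid: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    frame_phase: tuple[int, ...]
    q_value: float | None = None

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.segments)
        if total != 3 * len(self.plain_sequence):
            raise ValueError(
                f"{self.peptide_key}@{self.orf_id}: segment total {total} != 3x peptide length"
            )
        for (s1, e1), (s2, e2) in zip(self.segments, self.segments[1:]):
            if e1 > s2:
                raise ValueError(f"{self.peptide_key}@{self.orf_id}: segments overlap or unordered")


def project_interval(alignment: TranscriptGenomeAlignment, t_start: int, t_end: int
                     ) -> list[tuple[int, int]]:
    """Map a transcript interval through exon blocks to genome segments.

    Returns 0-based half-open genome intervals ordered by genome coordinate;
    an interval spanning a splice junction yields two or more segments.  On
    strand '-' a rising transcript coordinate maps to a falling genome
    coordinate within each block.
    """
    if not (0 <= t_start < t_end <= alignment.aligned_length):
        raise ProjectionError(
            f"{alignment.transcript_id}: interval [{t_start},{t_end}) escapes aligned "
            f"region [0,{alignment.aligned_length})"
        )
    segments: list[tuple[int, int]] = []
    for ts, te, gs, ge in alignment.blocks:
        lo, hi = max(t_start, ts), min(t_end, te)
        if lo >= hi:
            continue
        if alignment.strand == "+":
            segments.append((gs + (lo - ts), gs + (hi - ts)))
        else:
            segments.append((ge - (hi - ts), ge - (lo - ts)))
    segments.sort()
    return segments


def _phases(segments, strand: str) -> tuple[int, ...]:
    """GFF3 phase per genome-ordered segment.

    Phase of a coding segment is the count of bases to skip from its 5' end
    (reading direction) to reach a codon boundary; the first segment in
    translation order has phase 0 because peptides start on codon
    boundaries of their ORF.
    """
    order = range(len(segments)) if strand == "+" else range(len(segments) - 1, -1, -1)
    phases = [0] * len(segments)
    consumed = 0
    for i in order:
        phases[i] = (3 - consumed % 3) % 3
        consumed += segments[i][1] - segments[i][0]
    return tuple(phases)


def project_peptide(evidence: PeptideEvidence, orf: dict,
                    alignment: TranscriptGenomeAlignment,
                    plain_sequence: str | None = None,
                    q_value: float | None = None) -> GenomicPeptideFeature:
    """Project one peptide occurrence in an ORF into genome space.

    ``orf`` is an ORF-index entry (dict with transcript_id, frame, nt_start,
    nt_end) as produced by :func:`pitkit.orffinder.build_orf_database`.
    Protein offsets become transcript nucleotides (reverse frames reflect
    through the ORF's forward-strand interval), which are then pushed
    through the alignment.  Raises :class:`ProjectionError` when the ORF is
    not fully inside the aligned region.
    """
    frame = int(orf["frame"])
    nt_start, nt_end = int(orf["nt_start"]), int(orf["nt_end"])
    if frame > 0:
        t0 = nt_start + 3 * evidence.start
        t1 = nt_start + 3 * evidence.end
    else:
        # aa index 0 of a reverse-frame ORF sits at the forward-strand end
        t0 = nt_end - 3 * evidence.end
        t1 = nt_end - 3 * evidence.start
    segments = project_interval(alignment, t0, t1)
    strand = alignment.strand if frame > 0 else ("-" if alignment.strand == "+" else "+")
    plain = plain_sequence if plain_sequence is not None else evidence.peptide_key.split("#", 1)[0]
    return GenomicPeptideFeature(
        peptide_key=evidence.peptide_key,
        plain_sequence=plain,
        orf_id=orf["orf_id"],
        transcript_id=orf["transcript_id"],
        seqid=alignment.seqid,
        strand=strand,
        segments=tuple(segments),
        frame_phase=_phases(segments, strand),
        q_value=q_value,
    )


def to_cigar(feature: GenomicPeptideFeature, genome: dict[str, str] | None = None
             ) -> dict:
    """Render a projected feature as a SAM record dict.

    M runs cover the segments and N runs the gaps between consecutive
    segments; ``pos`` is the 1-based leftmost genome coordinate.  Reverse
    strand features set flag 16 and carry the reverse-complemented coding
    sequence (i.e. the forward-genome-strand bases), per SAM convention.
    ``genome`` (seqid -> sequence) supplies SEQ; without it SEQ is '*'.
    """
    ops = []
    prev_end = None
    for s, e in feature.segments:
        if prev_end is not None and s > prev_end:
            ops.append(f"{s - prev_end}N")
        ops.append(f"{e - s}M")
        prev_end = e
    seq = "*"
    if genome is not None:
        chrom = genome[feature.seqid]
        seq = "".join(chrom[s:e] for s, e in feature.segments)
    return {
        "qname": f"{feature.plain_sequence}|{feature.orf_id}",
        "flag": 16 if feature.strand == "-" else 0,
        "rname": feature.seqid,
        "pos": feature.segments[0][0] + 1,
        "cigar": "".join(ops),
        "seq": seq,
    }


@dataclass
class IntegrationResult:
    """Annotation bundle plus a run report of what could not be projected."""

    features: list[Gff3Feature] = field(default_factory=list)
    peptide_features: list[GenomicPeptideFeature] = field(default_factory=list)
    table: list[dict] = field(default_factory=list)
    unprojectable: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def write_gff3(self, path) -> None:
        write_gff3(self.features, path)

    def write_sam(self, path, reference_lengths: dict[str, int],
                  genome: dict[str, str] | None = None) -> None:
        records = [to_cigar(f, genome) for f in self.peptide_features]
        write_sam(records, reference_lengths, path)


def integrate(pags, peptides, evidence, orf_index, alignments) -> IntegrationResult:
    """Assemble the genome annotation bundle.

    Inputs: surviving :class:`ProteinAmbiguityGroup` list, retained scored
    peptides (for q-values; may be empty), peptide-to-ORF evidence, the ORF
    index from :func:`build_orf_database`, and transcript alignments.  The
    GFF3 hierarchy emitted is one mRNA with exon children per aligned
    transcript that carries an identified ORF, one CDS feature set per
    identified ORF (Parent = mRNA), and one peptide feature per projected
    occurrence (multi-segment peptides as multiple lines sharing an ID,
    Parent = CDS).  Unprojectable items are tallied, never silently dropped.
    """
    orf_by_id = {o["orf_id"]: o for o in orf_index}
    aln_by_tid = {a.transcript_id: a for a in alignments}
    q_by_key = {p.peptide_key: p.q_value for p in peptides}
    plain_by_key = {p.peptide_key: p.plain_sequence for p in peptides}

    identified_orfs: list[str] = []
    seen = set()
    for pag in pags:
        for acc in pag.members:
            if acc in seen:
                continue
            seen.add(acc)
            if acc not in orf_by_id:
                raise ValueError(f"PAG {pag.pag_id}: member {acc!r} absent from ORF index")
            identified_orfs.append(acc)

    result = IntegrationResult()
    used_transcripts: list[str] = []
    for orf_id in identified_orfs:
        tid = orf_by_id[orf_id]["transcript_id"]
        if tid not in aln_by_tid:
            result.unprojectable.append(f"{orf_id}: transcript {tid} has no genome alignment")
        elif tid not in used_transcripts:
            used_transcripts.append(tid)

    # mRNA + exon scaffolding
    for tid in used_transcripts:
        aln = aln_by_tid[tid]
        g_lo = min(b[2] for b in aln.blocks)
        g_hi = max(b[3] for b in aln.blocks)
        result.features.append(
            Gff3Feature(aln.seqid, "pitkit", "mRNA", g_lo + 1, g_hi, None, aln.strand, ".",
                        {"ID": tid, "Name": tid})
        )
        for i, (_, _, gs, ge) in enumerate(sorted(aln.blocks, key=lambda b: b[2]), 1):
            result.features.append(
                Gff3Feature(aln.seqid, "pitkit", "exon", gs + 1, ge, None, aln.strand, ".",
                            {"ID": f"{tid}.exon{i}", "Parent": tid})
            )

    # CDS per identified ORF
    for orf_id in identified_orfs:
        orf = orf_by_id[orf_id]
        tid = orf["transcript_id"]
        aln = aln_by_tid.get(tid)
        if aln is None:
            continue
        try:
            segs = project_interval(aln, int(orf["nt_start"]), int(orf["nt_end"]))
        except ProjectionError as exc:
            result.unprojectable.append(f"{orf_id}: {exc}")
            continue
        frame = int(orf["frame"])
        strand = aln.strand if frame > 0 else ("-" if aln.strand == "+" else "+")
        phases = _phases(segs, strand)
        for (gs, ge), ph in zip(segs, phases):
            result.features.append(
                Gff3Feature(aln.seqid, "pitkit", "CDS", gs + 1, ge, None, strand, ph,
                            {"ID": orf_id, "Parent": tid})
            )

    # peptide features
    ev_by_protein: dict[str, list[PeptideEvidence]] = {}
    for ev in evidence:
        ev_by_protein.setdefault(ev.protein_id, []).append(ev)
    for orf_id in identified_orfs:
        orf = orf_by_id[orf_id]
        aln = aln_by_tid.get(orf["transcript_id"])
        if aln is None:
            continue
        for n, ev in enumerate(ev_by_protein.get(orf_id, []), 1):
            try:
                feat = project_peptide(
                    ev, orf, aln,
                    plain_sequence=plain_by_key.get(ev.peptide_key),
                    q_value=q_by_key.get(ev.peptide_key),
                )
            except ProjectionError as exc:
                result.unprojectable.append(f"{ev.peptide_key}@{orf_id}: {exc}")
                continue
            result.peptide_features.append(feat)
            fid = f"{orf_id}.pep{n}"
            for (gs, ge), ph in zip(feat.segments, feat.frame_phase):
                result.features.append(
                    Gff3Feature(feat.seqid, "pitkit", "peptide", gs + 1, ge,
                                feat.q_value, feat.strand, ph,
                                {"ID": fid, "Parent": orf_id, "Name": feat.plain_sequence})
                )
            result.table.append(
                {
                    "peptide": feat.plain_sequence,
                    "orf_id": orf_id,
                    "transcript_id": feat.transcript_id,
                    "seqid": feat.seqid,
                    "strand": feat.strand,
                    "segments": ",".join(f"{s + 1}-{e}" for s, e in feat.segments),
                    "q_value": "" if feat.q_value is None else feat.q_value,
                }
            )

    result.counts = {
        "mRNA": len(used_transcripts),
        "CDS": len({f.attributes["ID"] for f in result.features if f.type == "CDS"}),
        "peptide_occurrences": len(result.peptide_features),
        "unprojectable": len(result.unprojectable),
    }
    return result


def extract_feature_sequence(feature: GenomicPeptideFeature, genome: dict[str, str]) -> str:
    """Splice-and-strand-aware nucleotide sequence of a projected feature."""
    chrom = genome[feature.seqid]
    nt = "".join(chrom[s:e] for s, e in feature.segments)
    return reverse_complement(nt) if feature.strand == "-" else nt
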