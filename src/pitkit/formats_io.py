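"""Readers and writers for the external formats the toolkit touches.

Strict, testable dialects: FASTA, tab-separated PSM tables, BLAST tabular
(outfmt 6), GFF3/GTF spliced-alignment input, GFF3 annotation output, and
SAM output.  All internal coordinates are 0-based half-open; conversion to
the 1-based inclusive convention of GFF3/SAM happens only at serialization.

Malformed input raises :class:`FormatError` by default; readers that accept
``errors="collect"`` instead return diagnostics alongside their records.
"""

from __future__ import annotations

import math
import re
import urllib.parse
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FormatError",
    "FastaRecord",
    "PsmRecord",
    "Gff3Feature",
    "BlastHit",
    "TranscriptGenomeAlignment",
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_blast_tabular",
    "read_transcript_alignments",
    "read_mzid_psms",
    "write_gff3",
    "read_gff3",
    "write_sam",
]


class FormatError(ValueError):
    """A file violated its declared dialect (message names the line)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry; ``id`` is the first whitespace-delimited header token."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from a search engine result table."""

    spectrum_id: str
    peptide: str
    score: float
    modifications: str = ""
    protein_hint: str = ""
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]+", self.peptide):
            raise ValueError(f"peptide {self.peptide!r} is not an uppercase residue string")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for spectrum {self.spectrum_id!r}")


@dataclass
class Gff3Feature:
    """One GFF3 line; start/end are 1-based inclusive as in the format."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    phase: int | str
    attributes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"feature {self.attributes.get('ID', '?')}: bad span {self.start}..{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"feature {self.attributes.get('ID', '?')}: bad strand {self.strand!r}")
        if str(self.phase) not in {"0", "1", "2", "."}:
            raise ValueError(f"feature {self.attributes.get('ID', '?')}: bad phase {self.phase!r}")


#: outfmt-6 column order (first 12 are mandatory)
BLAST6_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
)


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular (outfmt 6) hit; extra columns kept verbatim."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    extra: tuple[str, ...] = ()


@dataclass
class TranscriptGenomeAlignment:
    """A spliced transcript-to-genome alignment as ordered exon blocks.

    ``blocks`` is a list of ``(t_start, t_end, g_start, g_end)`` tuples with
    all coordinates 0-based half-open, sorted by transcript coordinate: the
    transcript intervals are contiguous and tile ``[0, aligned_length)``.
    On strand ``+`` genome intervals ascend along the list; on strand ``-``
    they descend, and within each block a rising transcript coordinate maps
    to a falling genome coordinate (so transcript position 0 sits in the
    block with the largest genome coordinate).
    """

    transcript_id: str
    seqid: str
    strand: str
    blocks: list[tuple[int, int, int, int]]

    @property
    def aligned_length(self) -> int:
        return self.blocks[-1][1] if self.blocks else 0

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        expect_t = 0
        prev_g: tuple[int, int] | None = None
        for ts, te, gs, ge in self.blocks:
            if te - ts != ge - gs or te <= ts:
                raise ValueError(f"{self.transcript_id}: malformed block {(ts, te, gs, ge)}")
            if ts != expect_t:
                raise ValueError(f"{self.transcript_id}: transcript intervals not contiguous")
            expect_t = te
            if prev_g is not None:
                lo, hi = (prev_g[1], gs) if self.strand == "+" else (ge, prev_g[0])
                if lo > hi:
                    raise ValueError(f"{self.transcript_id}: genome blocks overlap or misordered")
            prev_g = (gs, ge)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list[FastaRecord]:
    """Parse a FASTA file into records, preserving file order.

    Multi-line sequences are concatenated; CRLF endings tolerated.  A
    sequence line before any header, a duplicate id, or an entry with an
    empty sequence is a :class:`FormatError` naming the offending line.
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    header: tuple[str, str, int] | None = None  # id, description, line no
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rec_id, desc, lineno = header
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {rec_id!r} (line {lineno}) has an empty sequence")
        records.append(FastaRecord(rec_id, desc, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                rec_id, _, desc = head.partition(" ")
                if rec_id in seen:
                    raise FormatError(f"{path}: duplicate FASTA id {rec_id!r} at line {lineno}")
                seen.add(rec_id)
                header = (rec_id, desc.strip(), lineno)
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence line before any header at line {lineno}")
                chunks.append("".join(line.split()))
    flush()
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA with sequences wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# --------------------------------------------------------------------------
# PSM tables
# --------------------------------------------------------------------------

#: canonical PSM TSV column names
PSM_COLUMNS = ("spectrum_id", "peptide", "modifications", "score", "proteins")


def read_psm_table(path, score_direction: str = "higher_is_better") -> list[PsmRecord]:
    """Read the documented tab-separated PSM interchange format.

    Mandatory columns: ``spectrum_id``, ``peptide``, ``score``.  Optional:
    ``modifications`` and ``proteins`` (semicolon-joined accessions), which
    default to empty.  ``score_direction`` is recorded by the caller, not the
    table; it is accepted here only to validate the flag early.
    """
    if score_direction not in {"higher_is_better", "lower_is_better"}:
        raise ValueError(f"unknown score_direction {score_direction!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("spectrum_id", "peptide", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records: list[PsmRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), 2):  # header is line 1
        try:
            score = float(getattr(row, "score"))
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable score at line {idx}: {exc}") from None
        records.append(
            PsmRecord(
                spectrum_id=getattr(row, "spectrum_id"),
                peptide=getattr(row, "peptide"),
                score=score,
                modifications=getattr(row, "modifications", ""),
                protein_hint=getattr(row, "proteins", ""),
            )
        )
    return records


def write_psm_table(psms, path) -> None:
    pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "modifications": [p.modifications for p in psms],
            "score": [p.score for p in psms],
            "proteins": [p.protein_hint for p in psms],
        }
    ).to_csv(path, sep="\t", index=False)


def read_mzid_psms(path, decoy_prefix: str = "DECOY_") -> list[PsmRecord]:
    """Minimal mzIdentML 1.1 reader: one record per SpectrumIdentificationItem.

    Only the fields this toolkit consumes are extracted: spectrum id, peptide
    sequence, a score (the first numeric cvParam on the item, typically the
    engine's raw or E-value score; the caller sets the orientation) and the
    decoy flag of the matched evidence.  Full mzIdentML semantics are out of
    scope; the documented TSV is the primary interchange.
    """
    from lxml import etree

    def local(tag: str) -> str:
        return etree.QName(tag).localname

    peptides: dict[str, str] = {}
    db_accessions: dict[str, str] = {}
    evidences: dict[str, tuple[str, bool]] = {}  # id -> (peptide_ref, is_decoy-ish)
    records: list[PsmRecord] = []

    tree = etree.parse(str(path))
    root = tree.getroot()
    for el in root.iter():
        name = local(el.tag)
        if name == "DBSequence":
            db_accessions[el.get("id", "")] = el.get("accession", "")
        elif name == "Peptide":
            seq = next((c.text for c in el if local(c.tag) == "PeptideSequence"), None)
            if seq:
                peptides[el.get("id", "")] = seq.strip()
        elif name == "PeptideEvidence":
            acc = db_accessions.get(el.get("dBSequence_ref", ""), "")
            is_decoy = el.get("isDecoy", "false").lower() == "true" \
                or acc.startswith(decoy_prefix)
            evidences[el.get("id", "")] = (acc, is_decoy)

    for result in root.iter():
        if local(result.tag) != "SpectrumIdentificationResult":
            continue
        spectrum_id = result.get("spectrumID") or result.get("id", "")
        for item in result:
            if local(item.tag) != "SpectrumIdentificationItem":
                continue
            peptide = peptides.get(item.get("peptide_ref", ""))
            if not peptide:
                continue
            score = None
            accs: list[str] = []
            flags: list[bool] = []
            for child in item:
                cname = local(child.tag)
                if cname == "cvParam" and score is None:
                    try:
                        score = float(child.get("value", ""))
                    except ValueError:
                        pass
                elif cname == "PeptideEvidenceRef":
                    acc, dec = evidences.get(child.get("peptideEvidence_ref", ""), ("", False))
                    if acc:
                        accs.append(acc)
                    flags.append(dec)
            if score is None:
                continue
            records.append(
                PsmRecord(
                    spectrum_id=spectrum_id,
                    peptide=peptide,
                    score=score,
                    protein_hint=";".join(accs),
                    is_decoy=bool(flags) and all(flags),
                )
            )
    return records


# --------------------------------------------------------------------------
# BLAST tabular
# --------------------------------------------------------------------------

def read_blast_tabular(path) -> list[BlastHit]:
    """Parse BLAST outfmt-6 (12+ tab-separated columns); extras kept verbatim."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}: line {lineno}: expected >=12 tab-separated columns, got {len(parts)}")
            try:
                hit = BlastHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    extra=tuple(parts[12:]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if hit.evalue < 0 or not (0.0 <= hit.pct_identity <= 100.0):
                raise FormatError(f"{path}: line {lineno}: field out of range")
            hits.append(hit)
    return hits


def write_blast_tabular(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [h.query_id, h.subject_id, repr(h.pct_identity), str(h.aln_length),
                      str(h.mismatches), str(h.gap_opens), str(h.q_start), str(h.q_end),
                      str(h.s_start), str(h.s_end), repr(h.evalue), repr(h.bitscore),
                      *h.extra]
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# GFF3 / GTF
# --------------------------------------------------------------------------

_GFF3_ESCAPE_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "%;=&,\t"
)


def _escape_attr(value: str) -> str:
    return urllib.parse.quote(value, safe=_GFF3_ESCAPE_SAFE + " ")


def _unescape_attr(value: str) -> str:
    return urllib.parse.unquote(value)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = _unescape_attr(value.strip())
    return attrs


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for match in re.finditer(r'(\w+)\s+"([^"]*)"', text):
        attrs[match.group(1)] = match.group(2)
    return attrs


def read_gff3(path) -> list[Gff3Feature]:
    """Parse GFF3 (or attribute-quoted GTF) lines into features, in file order."""
    features: list[Gff3Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end < start")
            score = None if parts[5] == "." else float(parts[5])
            attr_text = parts[8]
            if "=" in attr_text.split(";")[0]:
                attrs = _parse_gff3_attributes(attr_text)
            else:
                attrs = _parse_gtf_attributes(attr_text)
            phase: int | str = "." if parts[7] == "." else int(parts[7])
            feat = Gff3Feature(parts[0], parts[1], parts[2], start, end, score, parts[6], phase, attrs)
            feat.validate()
            features.append(feat)
    return features


def write_gff3(features, path) -> None:
    """Serialize features to GFF3; refuses invalid features by ID."""
    for feat in features:
        try:
            feat.validate()
        except ValueError as exc:
            raise ValueError(f"refusing to write invalid feature: {exc}") from None
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={_escape_attr(v)}" for k, v in feat.attributes.items())
            score = "." if feat.score is None else f"{feat.score:g}"
            fh.write(
                "\t".join(
                    [feat.seqid, feat.source, feat.type, str(feat.start), str(feat.end),
                     score, feat.strand, str(feat.phase), attrs]
                )
                + "\n"
            )


def read_transcript_alignments(path, errors: str = "raise"):
    """Group exon features of a GMAP-style GFF3/GTF into alignment blocks.

    The transcript identifier of an exon is taken from, in priority order:
    its ``Parent`` attribute, ``transcript_id``, or the first token of
    ``Target``.  Exons of one transcript must share seqid and strand and must
    not overlap; violations reject that transcript with a diagnostic (fatal
    when ``errors="raise"``, collected when ``errors="collect"``).

    Returns a list of :class:`TranscriptGenomeAlignment`; with
    ``errors="collect"`` returns ``(alignments, diagnostics)``.
    """
    if errors not in {"raise", "collect"}:
        raise ValueError("errors must be 'raise' or 'collect'")
    exons: dict[str, list[Gff3Feature]] = {}
    order: list[str] = []
    for feat in read_gff3(path):
        if feat.type.lower() != "exon":
            continue
        tid = feat.attributes.get("Parent") or feat.attributes.get("transcript_id")
        if not tid:
            target = feat.attributes.get("Target", "")
            tid = target.split()[0] if target else None
        if not tid:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} has no transcript identifier")
        if tid not in exons:
            order.append(tid)
        exons.setdefault(tid, []).append(feat)

    alignments: list[TranscriptGenomeAlignment] = []
    diagnostics: list[str] = []
    for tid in order:
        feats = exons[tid]
        problem = None
        if len({f.seqid for f in feats}) > 1:
            problem = "exons on mixed seqids"
        elif len({f.strand for f in feats}) > 1:
            problem = "exons on mixed strands"
        if problem is None:
            spans = sorted((f.start - 1, f.end) for f in feats)  # to 0-based half-open
            if any(b[0] < a[1] for a, b in zip(spans, spans[1:])):
                problem = "overlapping exon blocks"
        if problem is not None:
            msg = f"{tid}: {problem}"
            if errors == "raise":
                raise FormatError(f"{path}: {msg}")
            diagnostics.append(msg)
            continue
        strand = feats[0].strand
        if strand not in "+-":
            strand = "+"
        # transcript order: genome-ascending on +, genome-descending on -
        ordered = spans if strand == "+" else spans[::-1]
        blocks: list[tuple[int, int, int, int]] = []
        t_off = 0
        for gs, ge in ordered:
            blocks.append((t_off, t_off + (ge - gs), gs, ge))
            t_off += ge - gs
        aln = TranscriptGenomeAlignment(tid, feats[0].seqid, strand, blocks)
        aln.validate()
        alignments.append(aln)
    if errors == "collect":
        return alignments, diagnostics
    return alignments


# --------------------------------------------------------------------------
# SAM
# --------------------------------------------------------------------------

def _cigar_reference_length(cigar: str) -> int:
    if cigar == "*":
        return 0
    total = 0
    for count, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MDN=X":
            total += int(count)
    return total


def write_sam(records, reference_lengths: dict[str, int], path) -> None:
    """Write SAM records (dicts with qname/flag/rname/pos/cigar/seq keys).

    ``pos`` is 1-based as in the format.  Each record's CIGAR
    reference-consumed length must fit inside the named reference; a record
    naming an unknown reference is an error.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            rname = rec["rname"]
            if rname not in reference_lengths:
                raise ValueError(f"record {rec['qname']!r}: unknown reference {rname!r}")
            pos = int(rec["pos"])
            ref_len = _cigar_reference_length(rec["cigar"])
            if pos < 1 or pos - 1 + ref_len > reference_lengths[rname]:
                raise ValueError(
                    f"record {rec['qname']!r}: alignment {pos}+{ref_len} exceeds {rname} length"
                )
            fh.write(
                "\t".join(
                    [
                        rec["qname"],
                        str(int(rec["flag"])),
                        rname,
                        str(pos),
                        str(int(rec.get("mapq", 255))),
                        rec["cigar"],
                        rec.get("rnext", "*"),
                        str(rec.get("pnext", 0)),
                        str(rec.get("tlen", 0)),
                        rec.get("seq", "*"),
                        rec.get("qual", "*"),
                    ]
                )
                + "\n"
            )
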