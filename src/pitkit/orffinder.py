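"""Six-frame open-reading-frame finder for assembled transcripts.

Builds a protein search database from the ORFs found in all six reading
frames of each transcript: frames +1/+2/+3 read the forward sequence at
offsets 0/1/2, frames -1/-2/-3 read the reverse complement at the same
offsets.  Candidate ORFs are maximal stop-free codon runs; the caller
chooses whether to keep only the longest per frame or everything above a
minimum length, whether an ORF must begin with ATG, and whether runs left
open at a transcript end count at all.

Coordinates of every reported ORF are given on the FORWARD transcript
strand as 0-based half-open nucleotide intervals, so downstream genome
projection never needs to know which strand the translation used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .formats_io import FastaRecord

__all__ = [
    "Transcript",
    "OrfParams",
    "OpenReadingFrame",
    "translate",
    "reverse_complement",
    "find_orfs",
    "build_orf_database",
]

FRAMES = (1, 2, 3, -1, -2, -3)

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript; U is normalized to T and case folded up."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"transcript {self.id!r} is empty")
        if not re.fullmatch(r"[ACGTN]+", seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"transcript {self.id!r}: invalid characters {bad}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class OrfParams:
    """Knobs of the ORF search.

    min_aa
        Minimum ORF length in residues (default 20 — the shortest length
        likely to yield a searchable tryptic peptide).
    mode
        ``per-frame-longest`` keeps at most one ORF per frame (the longest
        candidate, ties broken by smaller forward-strand start);
        ``all-above-min`` keeps every candidate of at least ``min_aa``.
    require_start
        Trim each candidate to its first ATG-encoded methionine.
    allow_partial
        Let runs that hit a transcript end (no bounding stop codon) count
        as candidates; de novo transcripts are frequently fragments, so the
        default keeps them.
    """

    min_aa: int = 20
    mode: str = "per-frame-longest"
    require_start: bool = False
    allow_partial: bool = True
    max_x_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if self.mode not in {"per-frame-longest", "all-above-min"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class OpenReadingFrame:
    orf_id: str
    transcript_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    nt_start: int  # 0-based half-open on the FORWARD transcript strand
    nt_end: int
    aa_sequence: str
    partial5: bool
    partial3: bool

    def __post_init__(self) -> None:
        if self.nt_end - self.nt_start != 3 * len(self.aa_sequence):
            raise ValueError(f"{self.orf_id}: span is not 3x protein length")
        if "*" in self.aa_sequence:
            raise ValueError(f"{self.orf_id}: stop symbol in protein sequence")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate with the standard genetic code (table 1).

    Any codon containing N yields 'X'; stop codons yield '*'.  The input
    length must be divisible by 3.
    """
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i:i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


@dataclass
class _Candidate:
    # coordinates on the reading strand (forward seq or its reverse complement)
    start: int
    end: int
    aa: str
    partial5: bool
    partial3: bool


def _frame_candidates(strand_seq: str, offset: int, params: OrfParams) -> list[_Candidate]:
    """Maximal stop-free codon runs in one frame of one strand."""
    n_codons = (len(strand_seq) - offset) // 3
    if n_codons <= 0:
        return []
    aa_frame = translate(strand_seq[offset:offset + 3 * n_codons])
    candidates: list[_Candidate] = []
    run_start = 0  # codon index of current run start
    for idx in range(n_codons + 1):
        at_end = idx == n_codons
        if at_end or aa_frame[idx] == "*":
            if idx > run_start:
                cand = _make_candidate(aa_frame, run_start, idx, offset, params,
                                       open3=at_end)
                if cand is not None:
                    candidates.append(cand)
            run_start = idx + 1
    return candidates


def _make_candidate(aa_frame: str, c_start: int, c_end: int, offset: int,
                    params: OrfParams, open3: bool) -> _Candidate | None:
    partial5 = c_start == 0
    partial3 = open3
    if open3 and not params.allow_partial:
        return None
    if params.require_start:
        rel = aa_frame.find("M", c_start, c_end)
        if rel == -1:
            return None
        c_start, partial5 = rel, False
    elif partial5 and not params.allow_partial:
        # no upstream stop bounds this run, so it is open at the 5' end
        return None
    aa = aa_frame[c_start:c_end]
    if len(aa) < params.min_aa:
        return None
    if aa.count("X") / len(aa) > params.max_x_fraction:
        return None
    return _Candidate(offset + 3 * c_start, offset + 3 * c_end, aa, partial5, partial3)


def find_orfs(transcript: Transcript, params: OrfParams | None = None) -> list[OpenReadingFrame]:
    """Find ORFs in all six frames; see :class:`OrfParams` for keep rules.

    Reverse-frame candidates are reported after conversion of their
    coordinates to the forward strand.  Ordinals in ``orf_id`` are assigned
    in order of forward-strand ``nt_start``.
    """
    params = params or OrfParams()
    seq = transcript.sequence
    length = len(seq)
    rc = reverse_complement(seq)

    collected: list[tuple[int, int, int, str, bool, bool]] = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        strand_seq = seq if frame > 0 else rc
        cands = _frame_candidates(strand_seq, offset, params)
        if params.mode == "per-frame-longest":
            if not cands:
                continue
            # longest; ties by smaller forward-strand nt_start
            def fwd_start(c: _Candidate) -> int:
                return c.start if frame > 0 else length - c.end
            cands = [min(cands, key=lambda c: (-len(c.aa), fwd_start(c)))]
        for c in cands:
            if frame > 0:
                nt_start, nt_end = c.start, c.end
            else:
                nt_start, nt_end = length - c.end, length - c.start
            collected.append((nt_start, nt_end, frame, c.aa, c.partial5, c.partial3))

    collected.sort(key=lambda t: (t[0], t[1], t[2]))
    orfs = []
    for ordinal, (nt_start, nt_end, frame, aa, p5, p3) in enumerate(collected, 1):
        frame_tag = f"F{'+' if frame > 0 else '-'}{abs(frame)}"
        orfs.append(
            OpenReadingFrame(
                orf_id=f"{transcript.id}|{frame_tag}|{ordinal}",
                transcript_id=transcript.id,
                frame=frame,
                nt_start=nt_start,
                nt_end=nt_end,
                aa_sequence=aa,
                partial5=p5,
                partial3=p3,
            )
        )
    return orfs


def build_orf_database(transcripts, params: OrfParams | None = None):
    """Run :func:`find_orfs` over transcripts and package the results.

    Returns ``(records, index)``: FASTA records (one per ORF, id = orf_id,
    description encoding provenance) and an index table (list of dicts, one
    per ORF) carrying everything genome projection needs — transcript id,
    frame, forward-strand coordinates, partial flags and the protein
    sequence itself.
    """
    params = params or OrfParams()
    seen: set[str] = set()
    records: list[FastaRecord] = []
    index: list[dict] = []
    for tr in transcripts:
        if tr.id in seen:
            raise ValueError(f"duplicate transcript id {tr.id!r}")
        seen.add(tr.id)
        for orf in find_orfs(tr, params):
            desc = (
                f"transcript={orf.transcript_id} frame={orf.frame:+d} "
                f"nt_start={orf.nt_start} nt_end={orf.nt_end} "
                f"partial5={orf.partial5} partial3={orf.partial3}"
            )
            records.append(FastaRecord(orf.orf_id, desc, orf.aa_sequence))
            index.append(
                {
                    "orf_id": orf.orf_id,
                    "transcript_id": orf.transcript_id,
                    "frame": orf.frame,
                    "nt_start": orf.nt_start,
                    "nt_end": orf.nt_end,
                    "partial5": orf.partial5,
                    "partial3": orf.partial3,
                    "aa_sequence": orf.aa_sequence,
                }
            )
    return records, index
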