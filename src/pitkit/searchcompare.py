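"""Comparison of identification lists from searches against different databases.

Two searches of the same spectra — e.g. against a reference proteome and
against a sample-specific ORF database — are compared at the peptide level
(exact plain-sequence overlap, with search-specific peptides attributed to
absence from the opposing database's in-silico tryptic universe) and at the
protein level (protein ambiguity groups matched through homology hits below
a strict e-value threshold, anchors first).  PAGs left unmatched are triaged
into explanatory categories using whatever auxiliary evidence is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from pyteomics import parser as _pyt_parser

__all__ = [
    "DigestParams",
    "PeptideOverlapReport",
    "PagMatchReport",
    "TriageEvidence",
    "UnmatchedClassification",
    "TRIAGE_CATEGORIES",
    "tryptic_digest",
    "compare_peptides",
    "match_pags",
    "classify_unmatched",
]

#: cleave C-terminal to K or R unless the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class DigestParams:
    """In-silico tryptic digest knobs.

    Search engines differ in how many missed cleavages they entertain, so
    the cap is exposed (default 2, a common engine default); the length
    window matches typical detectable tryptic peptides.
    """

    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 45


def tryptic_digest(protein: str, missed_cleavages: int = 2,
                   min_len: int = 7, max_len: int = 45) -> set[str]:
    """Fully tryptic peptides of one protein (K/R cleavage, KP/RP suppressed).

    Returns all fragments with at most ``missed_cleavages`` internal
    cleavage sites and length within ``[min_len, max_len]``; pass
    ``min_len=1, max_len=10**9`` to disable the filter.
    """
    peptides = _pyt_parser.cleave(protein, TRYPSIN_RULE, missed_cleavages)
    return {p for p in peptides if min_len <= len(p) <= max_len}


# --------------------------------------------------------------------------
# peptide-level overlap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideOverlapReport:
    n_a: int
    n_b: int
    shared: int
    unique_a: int
    unique_b: int
    overlap_pct: int
    absent_from_other_db_a: int
    absent_from_other_db_b: int
    absent_pct_a: float
    absent_pct_b: float

    @staticmethod
    def overlap_percent(shared: int, unique_a: int, unique_b: int) -> int:
        """Shared / union of the two retained sets, as a rounded percentage."""
        union = shared + unique_a + unique_b
        return round(100 * shared / union) if union else 100

    @staticmethod
    def absence_percent(absent: int, unique: int) -> float:
        """Fraction of one search's unique peptides missing from the other
        database's digest universe, as a percentage truncated to one decimal
        (the convention of the comparison tables this reproduces)."""
        if not unique:
            return 0.0
        return math.floor(1000 * absent / unique) / 10

    @classmethod
    def from_counts(cls, shared: int, unique_a: int, unique_b: int,
                    absent_a: int = 0, absent_b: int = 0) -> "PeptideOverlapReport":
        return cls(
            n_a=shared + unique_a,
            n_b=shared + unique_b,
            shared=shared,
            unique_a=unique_a,
            unique_b=unique_b,
            overlap_pct=cls.overlap_percent(shared, unique_a, unique_b),
            absent_from_other_db_a=absent_a,
            absent_from_other_db_b=absent_b,
            absent_pct_a=cls.absence_percent(absent_a, unique_a),
            absent_pct_b=cls.absence_percent(absent_b, unique_b),
        )


def compare_peptides(retained_a, retained_b, db_a=None, db_b=None,
                     digest_params: DigestParams | None = None) -> PeptideOverlapReport:
    """Exact plain-sequence overlap of two retained peptide lists.

    ``retained_a``/``retained_b`` are iterables of plain peptide sequences.
    When the protein databases are supplied, each search's unique peptides
    are checked against the opposing database's tryptic universe: a unique
    peptide absent there could never have been found by the other search,
    which attributes the difference to database content rather than scoring.
    """
    digest_params = digest_params or DigestParams()
    set_a, set_b = set(retained_a), set(retained_b)
    shared = set_a & set_b
    unique_a, unique_b = set_a - set_b, set_b - set_a

    absent_a = absent_b = 0
    if db_b is not None and unique_a:
        universe_b = set()
        for rec in db_b:
            universe_b |= tryptic_digest(rec.sequence, digest_params.missed_cleavages,
                                         digest_params.min_len, digest_params.max_len)
        absent_a = sum(1 for p in unique_a if p not in universe_b)
    if db_a is not None and unique_b:
        universe_a = set()
        for rec in db_a:
            universe_a |= tryptic_digest(rec.sequence, digest_params.missed_cleavages,
                                         digest_params.min_len, digest_params.max_len)
        absent_b = sum(1 for p in unique_b if p not in universe_a)

    return PeptideOverlapReport.from_counts(
        len(shared), len(unique_a), len(unique_b), absent_a, absent_b
    )


# --------------------------------------------------------------------------
# PAG matching through homology
# --------------------------------------------------------------------------

@dataclass
class PagMatchReport:
    anchor_anchor: int
    anchor_submember: int
    unmatched_a: list[str]
    unmatched_b: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    @property
    def total_matches(self) -> int:
        return self.anchor_anchor + self.anchor_submember

    @property
    def pag_overlap_pct(self) -> int:
        denom = self.total_matches + len(self.unmatched_a) + len(self.unmatched_b)
        return round(100 * self.total_matches / denom) if denom else 100

    @staticmethod
    def overlap_percent(total_matches: int, n_unmatched_a: int, n_unmatched_b: int) -> int:
        denom = total_matches + n_unmatched_a + n_unmatched_b
        return round(100 * total_matches / denom) if denom else 100


def _membership(pags) -> dict[str, list[tuple[str, bool]]]:
    """accession -> [(pag_id, is_anchor), ...]"""
    out: dict[str, list[tuple[str, bool]]] = {}
    for pag in pags:
        out.setdefault(pag.anchor_id, []).append((pag.pag_id, True))
        for acc in (*pag.same_set_members, *pag.sub_members):
            out.setdefault(acc, []).append((pag.pag_id, False))
    return out


def match_pags(pags_a, pags_b, hits, evalue_threshold: float = 1e-30) -> PagMatchReport:
    """Match PAGs across searches through homology hits.

    A hit qualifies only when its e-value is strictly below the threshold.
    Matching is greedy and uses each PAG at most once: pass 1 pairs anchors
    with anchors, pass 2 pairs anchors of one side with same-set or
    sub-members of the other, both passes scanning candidates by ascending
    e-value with ties broken on the normalized accession pair.  Hits naming
    accessions in neither PAG list are ignored with a diagnostic.
    """
    members_a, members_b = _membership(pags_a), _membership(pags_b)
    diagnostics: list[str] = []

    candidates = []  # (evalue, norm pair, pag_a, pag_b, anchor_a, anchor_b)
    for hit in hits:
        qa, sb = hit.query_id, hit.subject_id
        in_a, in_b = qa in members_a, sb in members_b
        if not (in_a and in_b):
            # allow the hit file to be oriented either way
            if sb in members_a and qa in members_b:
                qa, sb = sb, qa
                in_a = in_b = True
        if not (in_a and in_b):
            diagnostics.append(f"hit {hit.query_id}->{hit.subject_id} names unknown accession")
            continue
        if not hit.evalue < evalue_threshold:
            continue
        for pag_a, a_anchor in members_a[qa]:
            for pag_b, b_anchor in members_b[sb]:
                candidates.append(
                    (hit.evalue, tuple(sorted((qa, sb))), (qa, sb), pag_a, pag_b, a_anchor, b_anchor)
                )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    anchor_anchor = 0
    for ev, _, _, pag_a, pag_b, a_anchor, b_anchor in candidates:
        if a_anchor and b_anchor and pag_a not in used_a and pag_b not in used_b:
            used_a.add(pag_a)
            used_b.add(pag_b)
            pairs.append((pag_a, pag_b))
            anchor_anchor += 1
    anchor_submember = 0
    for ev, _, _, pag_a, pag_b, a_anchor, b_anchor in candidates:
        if (a_anchor or b_anchor) and pag_a not in used_a and pag_b not in used_b:
            used_a.add(pag_a)
            used_b.add(pag_b)
            pairs.append((pag_a, pag_b))
            anchor_submember += 1

    unmatched_a = [p.pag_id for p in pags_a if p.pag_id not in used_a]
    unmatched_b = [p.pag_id for p in pags_b if p.pag_id not in used_b]
    return PagMatchReport(anchor_anchor, anchor_submember, unmatched_a, unmatched_b,
                          pairs, diagnostics)


# --------------------------------------------------------------------------
# triage of unmatched PAGs
# --------------------------------------------------------------------------

TRIAGE_CATEGORIES = (
    "isoform_of_matched",
    "no_transcript_evidence",
    "assembly_failure",
    "orf_failure",
    "single_peptide_in_other_search",
    "extended_orf",
    "no_known_homology",
)


@dataclass(frozen=True)
class UnmatchedClassification:
    pag_id: str
    category: str


@dataclass
class TriageEvidence:
    """Auxiliary evidence for classifying unmatched PAGs; fields left None
    disable the category that depends on them (recorded, never a crash).

    matched_accessions
        Accessions that participated in a counted cross-search match.
    has_transcript
        accession -> whether any transcript covers the protein's locus.
    assembly_expected
        accession -> whether a transcript should have been assembled (its
        absence is then an assembler failure rather than missing
        expression).
    orf_survives
        accession -> whether an ORF of the protein exists in the other
        search's database.
    other_search_peptide_count
        accession -> distinct-peptide count in the other search.
    orf_extends_reference
        accession -> whether the matching ORF strictly contains the
        reference protein with extra peptide evidence in the extension.
    """

    matched_accessions: set[str] | None = None
    has_transcript: dict[str, bool] | None = None
    assembly_expected: dict[str, bool] | None = None
    orf_survives: dict[str, bool] | None = None
    other_search_peptide_count: dict[str, int] | None = None
    orf_extends_reference: dict[str, bool] | None = None
    disabled_categories: list[str] = field(default_factory=list)


def classify_unmatched(unmatched_pags, evidence: TriageEvidence
                       ) -> list[UnmatchedClassification]:
    """Assign exactly one explanatory category per unmatched PAG.

    The decision cascade, first hit wins: (1) a member of the PAG took part
    in a counted match -> isoform_of_matched; (2) no transcript covers the
    protein -> assembly_failure when a transcript was expected, else
    no_transcript_evidence; (3) transcripts exist but no ORF of the protein
    survives -> orf_failure; (4) the other search saw the protein with
    exactly one peptide -> single_peptide_in_other_search; (5) the ORF
    strictly extends the reference protein with extra evidence ->
    extended_orf; (6) no_known_homology otherwise.
    """
    ev = evidence
    if ev.matched_accessions is None:
        ev.disabled_categories.append("isoform_of_matched")
    if ev.has_transcript is None:
        ev.disabled_categories.append("no_transcript_evidence")
        ev.disabled_categories.append("orf_failure")
    if ev.assembly_expected is None and "assembly_failure" not in ev.disabled_categories:
        ev.disabled_categories.append("assembly_failure")
    if ev.other_search_peptide_count is None:
        ev.disabled_categories.append("single_peptide_in_other_search")
    if ev.orf_extends_reference is None:
        ev.disabled_categories.append("extended_orf")

    out = []
    for pag in unmatched_pags:
        members = pag.members
        anchor = pag.anchor_id
        category = "no_known_homology"
        if ev.matched_accessions is not None and any(m in ev.matched_accessions for m in members):
            category = "isoform_of_matched"
        elif ev.has_transcript is not None and not ev.has_transcript.get(anchor, False):
            if ev.assembly_expected is not None and ev.assembly_expected.get(anchor, False):
                category = "assembly_failure"
            else:
                category = "no_transcript_evidence"
        elif ev.has_transcript is not None and ev.orf_survives is not None \
                and not ev.orf_survives.get(anchor, False):
            category = "orf_failure"
        elif ev.other_search_peptide_count is not None \
                and ev.other_search_peptide_count.get(anchor, 0) == 1:
            category = "single_peptide_in_other_search"
        elif ev.orf_extends_reference is not None \
                and ev.orf_extends_reference.get(anchor, False):
            category = "extended_orf"
        out.append(UnmatchedClassification(pag.pag_id, category))
    return out
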