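"""Post-processing of peptide-spectrum matches: decoys, FDR, protein inference.

The chain mirrors standard shotgun-proteomics practice: append a reversed
decoy database, collapse PSMs to their best evidence per peptide, estimate
peptide-level q-values by target-decoy counting, filter at an FDR threshold,
map surviving peptides onto proteins by exact substring search, and collapse
proteins sharing peptide evidence into protein ambiguity groups (PAGs) with
an anchor protein carrying the most evidence.

Two distinct peptide identities are used deliberately: FDR bookkeeping keys
on sequence *plus* modification string, while cross-search overlap elsewhere
in the toolkit compares plain sequences only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .formats_io import FastaRecord, PsmRecord

__all__ = [
    "ScoredPeptide",
    "PeptideEvidence",
    "ProteinAmbiguityGroup",
    "DECOY_PREFIX",
    "generate_decoy_database",
    "peptide_level_scores",
    "compute_q_values",
    "filter_peptides",
    "map_peptides_to_proteins",
    "group_proteins",
]

DECOY_PREFIX = "DECOY_"


@dataclass
class ScoredPeptide:
    """A peptide collapsed to its best PSM, later annotated with a q-value."""

    peptide_key: str  # sequence + modification string
    plain_sequence: str
    best_score: float
    is_decoy: bool
    supporting_spectra: int
    q_value: float | None = None


@dataclass(frozen=True)
class PeptideEvidence:
    """One exact occurrence of a peptide inside a protein."""

    peptide_key: str
    protein_id: str
    start: int  # 0-based offset in the protein
    end: int  # half-open


@dataclass
class ProteinAmbiguityGroup:
    pag_id: str
    anchor_id: str
    same_set_members: list[str] = field(default_factory=list)
    sub_members: list[str] = field(default_factory=list)
    peptide_keys: frozenset[str] = frozenset()

    @property
    def members(self) -> list[str]:
        return [self.anchor_id, *self.same_set_members, *self.sub_members]


# --------------------------------------------------------------------------
# decoy construction
# --------------------------------------------------------------------------

def generate_decoy_database(records, prefix: str = DECOY_PREFIX) -> list[FastaRecord]:
    """Append one reversed-sequence decoy per target record.

    Reversal preserves length and amino-acid composition, so decoy matches
    are score-distributed like chance target matches.  Output is all targets
    followed by all decoys.  A target id already carrying the prefix would
    corrupt decoy detection downstream and is an error.
    """
    decoys = []
    for rec in records:
        if rec.id.startswith(prefix):
            raise ValueError(f"target id {rec.id!r} already bears the decoy prefix {prefix!r}")
        decoys.append(FastaRecord(prefix + rec.id, "reversed decoy", rec.sequence[::-1]))
    return list(records) + decoys


# --------------------------------------------------------------------------
# peptide-level collapse and q-values
# --------------------------------------------------------------------------

def peptide_key_of(psm: PsmRecord) -> str:
    return psm.peptide if not psm.modifications else f"{psm.peptide}#{psm.modifications}"


def _psm_is_decoy(psm: PsmRecord, decoy_prefix: str) -> bool:
    if psm.protein_hint:
        accs = [a for a in psm.protein_hint.split(";") if a]
        return all(a.startswith(decoy_prefix) for a in accs)
    return psm.is_decoy


def peptide_level_scores(psms, higher_is_better: bool = True,
                         decoy_prefix: str = DECOY_PREFIX) -> list[ScoredPeptide]:
    """Collapse PSMs to one :class:`ScoredPeptide` per peptide key.

    The peptide key is sequence plus modification string; the best score is
    the maximum (or minimum, for ``higher_is_better=False``) over the
    peptide's PSMs.  A peptide with evidence in both target and decoy
    proteins counts as target.
    """
    groups: dict[str, list[PsmRecord]] = defaultdict(list)
    for psm in psms:
        groups[peptide_key_of(psm)].append(psm)
    best = max if higher_is_better else min
    out = []
    for key, members in groups.items():
        out.append(
            ScoredPeptide(
                peptide_key=key,
                plain_sequence=members[0].peptide,
                best_score=best(p.score for p in members),
                is_decoy=all(_psm_is_decoy(p, decoy_prefix) for p in members),
                supporting_spectra=len(members),
            )
        )
    return out


def compute_q_values(peptides, higher_is_better: bool = True,
                     estimator: str = "simple") -> list[ScoredPeptide]:
    """Assign target-decoy q-values to scored peptides.

    Peptides are ranked best score first (ties: decoys before targets, the
    conservative order).  At each rank the FDR estimate is D/max(T,1) with
    ``estimator="simple"`` or (2D)/(T+D) with ``estimator="concatenated"``,
    where D and T count decoys and targets at that rank or better.  The
    q-value is the minimum estimate at this rank or any worse rank, capped
    at 1.  The input list is returned sorted in ranking order.
    """
    if estimator not in {"simple", "concatenated"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    sign = -1.0 if higher_is_better else 1.0
    ranked = sorted(peptides, key=lambda p: (sign * p.best_score, not p.is_decoy))
    fdrs = []
    n_decoy = n_target = 0
    for pep in ranked:
        if pep.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if estimator == "simple":
            fdr = n_decoy / max(n_target, 1)
        else:
            fdr = 2 * n_decoy / (n_target + n_decoy)
        fdrs.append(min(fdr, 1.0))
    running = 1.0
    for i in range(len(ranked) - 1, -1, -1):
        running = min(running, fdrs[i])
        ranked[i].q_value = running
    return ranked


def filter_peptides(peptides, threshold: float = 0.01) -> list[ScoredPeptide]:
    """Keep target peptides with q-value at or below the FDR threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    out = []
    for pep in peptides:
        if pep.q_value is None:
            raise ValueError(f"peptide {pep.peptide_key!r} has no q-value; run compute_q_values first")
        if not pep.is_decoy and pep.q_value <= threshold:
            out.append(pep)
    return out


# --------------------------------------------------------------------------
# peptide-to-protein mapping
# --------------------------------------------------------------------------

def _all_occurrences(needle: str, haystack: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def map_peptides_to_proteins(peptides, database, equate_il: bool = False,
                             decoy_prefix: str = DECOY_PREFIX):
    """Exact-substring mapping of retained peptides onto target proteins.

    Every occurrence in every target protein is reported (decoy entries in
    the database are skipped).  ``equate_il=True`` treats isoleucine and
    leucine as indistinguishable, as some search engines do; the default
    keeps them distinct.  Returns ``(evidences, unmapped_keys)``.
    """
    def norm(seq: str) -> str:
        return seq.replace("I", "L") if equate_il else seq

    evidences: list[PeptideEvidence] = []
    mapped: set[str] = set()
    targets = [rec for rec in database if not rec.id.startswith(decoy_prefix)]
    normed = [(rec, norm(rec.sequence)) for rec in targets]
    for pep in peptides:
        needle = norm(pep.plain_sequence)
        for rec, seq in normed:
            for start in _all_occurrences(needle, seq):
                evidences.append(
                    PeptideEvidence(pep.peptide_key, rec.id, start, start + len(needle))
                )
                mapped.add(pep.peptide_key)
    unmapped = [p.peptide_key for p in peptides if p.peptide_key not in mapped]
    return evidences, unmapped


# --------------------------------------------------------------------------
# protein ambiguity grouping
# --------------------------------------------------------------------------

def group_proteins(evidence, min_peptides: int = 2,
                   count_plain_sequences: bool = True) -> list[ProteinAmbiguityGroup]:
    """Collapse proteins sharing peptide evidence into ambiguity groups.

    Proteins are visited by distinct-peptide count descending, accession
    ascending.  A protein whose peptide set equals an existing group
    anchor's set joins it as a same-set member; a proper subset joins the
    first qualifying group (creation order) as a sub-member; anything else
    founds a new group and becomes its anchor.  Groups whose anchor has
    fewer than ``min_peptides`` distinct peptides are finally discarded
    (the classical two-peptide rule at the default).

    ``count_plain_sequences`` applies the two-peptide rule to distinct
    unmodified sequences rather than modified peptide keys.
    """
    pep_sets: dict[str, set[str]] = defaultdict(set)
    for ev in evidence:
        pep_sets[ev.protein_id].add(ev.peptide_key)

    order = sorted(pep_sets, key=lambda acc: (-len(pep_sets[acc]), acc))
    groups: list[ProteinAmbiguityGroup] = []
    for acc in order:
        pset = pep_sets[acc]
        placed = False
        for grp in groups:
            if pset == grp.peptide_keys:
                grp.same_set_members.append(acc)
                placed = True
                break
        if placed:
            continue
        for grp in groups:
            if pset < grp.peptide_keys:
                grp.sub_members.append(acc)
                placed = True
                break
        if not placed:
            groups.append(
                ProteinAmbiguityGroup(
                    pag_id=f"PAG_{len(groups) + 1:05d}",
                    anchor_id=acc,
                    peptide_keys=frozenset(pset),
                )
            )

    def distinct_count(keys: frozenset[str]) -> int:
        if count_plain_sequences:
            return len({k.split("#", 1)[0] for k in keys})
        return len(keys)

    return [g for g in groups if distinct_count(g.peptide_keys) >= min_peptides]
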