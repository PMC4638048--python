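"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a result through a deliberately different route from
the implementation it checks: explicit enumeration, frozen reference tables,
or direct sequence extraction, never the library's own code path.
"""

from __future__ import annotations

from itertools import product

# Standard genetic code in TCAG x TCAG x TCAG order — the classic 64-letter
# reference string, frozen here independently of any codon-table library.
GENETIC_CODE_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_TO_AA = {
    "".join(codon): aa
    for codon, aa in zip(product("TCAG", repeat=3), GENETIC_CODE_TCAG)
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_translate(codon: str) -> str:
    return "X" if "N" in codon else CODON_TO_AA[codon]


def oracle_find_orfs(sequence: str, min_aa: int, mode: str, require_start: bool,
                     allow_partial: bool, max_x_fraction: float = 0.5):
    """Enumerate every maximal stop-free codon pair in all six frames.

    Returns a sorted list of (nt_start, nt_end, frame, aa) tuples on the
    forward strand, applying the same keep rules as the ORF finder but via
    exhaustive start/stop pair enumeration.
    """
    length = len(sequence)
    kept = []
    for frame in (1, 2, 3, -1, -2, -3):
        offset = abs(frame) - 1
        strand_seq = sequence if frame > 0 else oracle_revcomp(sequence)
        n = (len(strand_seq) - offset) // 3
        aas = [oracle_translate(strand_seq[offset + 3 * i: offset + 3 * i + 3])
               for i in range(n)]
        candidates = []
        # every codon index pair (i, j), kept only if it is a maximal run
        for i in range(n):
            for j in range(i + 1, n + 1):
                if "*" in aas[i:j]:
                    continue
                left_maximal = i == 0 or aas[i - 1] == "*"
                right_maximal = j == n or aas[j] == "*"
                if not (left_maximal and right_maximal):
                    continue
                open3 = j == n
                open5 = i == 0
                start = i
                if open3 and not allow_partial:
                    continue
                if require_start:
                    ms = [k for k in range(i, j) if aas[k] == "M"]
                    if not ms:
                        continue
                    start = ms[0]
                elif open5 and not allow_partial:
                    continue
                aa = "".join(aas[start:j])
                if len(aa) < min_aa:
                    continue
                if aa.count("X") / len(aa) > max_x_fraction:
                    continue
                candidates.append((start, j, aa))
        results = []
        for start, j, aa in candidates:
            s_on_strand = offset + 3 * start
            e_on_strand = offset + 3 * j
            if frame > 0:
                nt_start, nt_end = s_on_strand, e_on_strand
            else:
                nt_start, nt_end = length - e_on_strand, length - s_on_strand
            results.append((nt_start, nt_end, frame, aa))
        if mode == "per-frame-longest":
            if results:
                results = [min(results, key=lambda r: (-len(r[3]), r[0]))]
        kept.extend(results)
    return sorted(kept)


def oracle_digest(protein: str, missed_cleavages: int, min_len: int, max_len: int):
    """Enumerate all substrings and test the tryptic boundary rules."""
    n = len(protein)

    def is_site(i: int) -> bool:  # cleavage between i and i+1
        return protein[i] in "KR" and (i + 1 >= n or protein[i + 1] != "P")

    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            left_ok = i == 0 or is_site(i - 1)
            right_ok = j == n or is_site(j - 1)
            if not (left_ok and right_ok):
                continue
            internal = sum(1 for k in range(i, j - 1) if is_site(k))
            if internal > missed_cleavages:
                continue
            if min_len <= j - i <= max_len:
                out.add(protein[i:j])
    return out


def oracle_group(peptide_sets: dict[str, frozenset], min_peptides: int):
    """Straightforward re-derivation of ambiguity grouping.

    Returns a list of (anchor, same_set tuple, sub tuple, peptide frozenset)
    in group-creation order, after the minimum-peptide rule.
    """
    order = sorted(peptide_sets, key=lambda a: (-len(peptide_sets[a]), a))
    groups = []  # [anchor, [same], [sub], set]
    for acc in order:
        s = peptide_sets[acc]
        target = next((g for g in groups if s == g[3]), None)
        if target is not None:
            target[1].append(acc)
            continue
        target = next((g for g in groups if s < g[3]), None)
        if target is not None:
            target[2].append(acc)
            continue
        groups.append([acc, [], [], s])
    return [
        (g[0], tuple(g[1]), tuple(g[2]), frozenset(g[3]))
        for g in groups
        if len(g[3]) >= min_peptides
    ]


def oracle_match_totals(anchors_a, members_a, anchors_b, members_b, hits, threshold):
    """One-use greedy matcher over explicit candidate lists.

    ``hits`` is a list of (acc_a, acc_b, evalue); membership dicts map
    accession -> pag id and anchor dicts are sets of anchor accessions.
    Returns (anchor_anchor, anchor_submember).
    """
    cands = []
    for qa, sb, ev in hits:
        if ev >= threshold:
            continue
        if qa not in members_a or sb not in members_b:
            continue
        cands.append((ev, tuple(sorted((qa, sb))), (qa, sb)))
    cands.sort()
    used_a, used_b = set(), set()
    aa = sub = 0
    for _, _, (qa, sb) in cands:
        pa, pb = members_a[qa], members_b[sb]
        if pa in used_a or pb in used_b:
            continue
        if qa in anchors_a and sb in anchors_b:
            used_a.add(pa)
            used_b.add(pb)
            aa += 1
    for _, _, (qa, sb) in cands:
        pa, pb = members_a[qa], members_b[sb]
        if pa in used_a or pb in used_b:
            continue
        if qa in anchors_a or sb in anchors_b:
            used_a.add(pa)
            used_b.add(pb)
            sub += 1
    return aa, sub


def oracle_find_orfs_fast(sequence: str, min_aa: int, mode: str, require_start: bool,
                          allow_partial: bool, max_x_fraction: float = 0.5):
    """Linear-time oracle: maximal runs delimited by stop codon positions.

    Same keep rules and output shape as :func:`oracle_find_orfs`, derived
    from the stop-position list instead of pair enumeration, for long
    transcripts.
    """
    length = len(sequence)
    kept = []
    for frame in (1, 2, 3, -1, -2, -3):
        offset = abs(frame) - 1
        strand_seq = sequence if frame > 0 else oracle_revcomp(sequence)
        n = (len(strand_seq) - offset) // 3
        aas = [oracle_translate(strand_seq[offset + 3 * i: offset + 3 * i + 3])
               for i in range(n)]
        stops = [i for i, a in enumerate(aas) if a == "*"]
        lefts = [0] + [s + 1 for s in stops]
        rights = stops + [n]
        results = []
        for i, j in zip(lefts, rights):
            if j <= i:
                continue
            open3 = j == n
            open5 = i == 0
            start = i
            if open3 and not allow_partial:
                continue
            if require_start:
                ms = [k for k in range(i, j) if aas[k] == "M"]
                if not ms:
                    continue
                start = ms[0]
            elif open5 and not allow_partial:
                continue
            aa = "".join(aas[start:j])
            if len(aa) < min_aa:
                continue
            if aa.count("X") / len(aa) > max_x_fraction:
                continue
            s_on, e_on = offset + 3 * start, offset + 3 * j
            if frame > 0:
                results.append((s_on, e_on, frame, aa))
            else:
                results.append((length - e_on, length - s_on, frame, aa))
        if mode == "per-frame-longest" and results:
            results = [min(results, key=lambda r: (-len(r[3]), r[0]))]
        kept.extend(results)
    return sorted(kept)
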