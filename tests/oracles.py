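"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with apmsref.digest: cleavage sites are
enumerated by direct string scanning and peptides by substring slicing.
"""

from __future__ import annotations

MET_EXCISION_SECOND = set("ACGPSTV")


def cleavage_points(seq: str, cleave_after=frozenset("KR"), suppress_p=True) -> list[int]:
    """0-based positions i such that a cut falls between seq[i-1] and seq[i]."""
    pts = []
    for i in range(1, len(seq)):
        if seq[i - 1] in cleave_after and not (suppress_p and seq[i] == "P"):
            pts.append(i)
    return pts


def brute_force_digest(
    seq: str,
    max_missed: int = 1,
    min_length: int = 7,
    cleave_after=frozenset("KR"),
    suppress_p: bool = True,
) -> set[tuple[str, int, int]]:
    """All digest products as (sequence, start, end), 1-based inclusive."""
    bounds = [0] + cleavage_points(seq, cleave_after, suppress_p) + [len(seq)]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            pep = seq[bounds[a] : bounds[b]]
            if len(pep) >= min_length:
                out.add((pep, bounds[a] + 1, bounds[b]))
    return out


def substring_occurrences(
    peptide: str, seq: str, max_missed: int = 1, suppress_p: bool = True
) -> set[str]:
    """Occurrence kinds of ``peptide`` in ``seq`` by naive substring scan.

    Kinds mirror the digestion-boundary definition: ``nterm`` (valid
    tryptic peptide starting at residue 1), ``internal`` (valid tryptic
    occurrence elsewhere), ``nterm_excised`` (the Met-excised first
    peptide). Boundary validity and missed-cleavage counting are derived
    from scratch at every match position.
    """
    kinds: set[str] = set()
    pts = set(cleavage_points(seq, suppress_p=suppress_p))
    start = 0
    while True:
        i = seq.find(peptide, start)
        if i < 0:
            break
        j = i + len(peptide)
        start_ok = i == 0 or i in pts
        end_ok = j == len(seq) or j in pts
        internal = sum(1 for k in range(i + 1, j) if k in pts)
        if start_ok and end_ok and internal <= max_missed:
            kinds.add("nterm" if i == 0 else "internal")
        start = i + 1
    if (
        len(seq) > 1
        and seq[0] == "M"
        and seq[1] in MET_EXCISION_SECOND
    ):
        first_cut = min((p for p in sorted(pts)), default=len(seq))
        if peptide == seq[1:first_cut]:
            kinds.add("nterm_excised")
    return kinds


def brute_force_classify(peptide: str, sequences: dict[str, str], max_missed: int = 1):
    """(kind, carrying ids) by the naive scan; None if absent everywhere."""
    occ = {
        pid: k
        for pid, s in sequences.items()
        if (k := substring_occurrences(peptide, s, max_missed))
    }
    if not occ:
        return None
    if len(occ) == 1:
        return "unique", frozenset(occ)
    nterm_met = any("nterm" in k for k in occ.values()) and peptide.startswith("M")
    internal_only = any(k == {"internal"} for k in occ.values())
    if nterm_met and internal_only:
        return "ambiguous_nterm", frozenset(occ)
    return "shared", frozenset(occ)


def brute_force_nsaf(counts: dict[str, float], lengths: dict[str, float]) -> dict[str, float]:
    """NSAF by explicit summation, no vectorisation."""
    saf = {p: counts[p] / lengths[p] for p in counts}
    total = 0.0
    for v in saf.values():
        total += v
    return {p: v / total for p, v in saf.items()}
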