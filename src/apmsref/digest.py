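"""In-silico tryptic digestion and proteoform-unique peptide classification.

Trypsin cleaves C-terminal to K/R but not before proline (the classical
Keil-style suppression); up to ``max_missed_cleavages`` internal sites may
remain uncut. Co-translational N-terminal processing is modelled as
initiator-Met excision (when residue 2 is small: A/C/G/P/S/T/V) plus
optional N-terminal acetylation, tracked as a nominal +42 Da delta. A
peptide observed in an experiment is classified as unique to one isoform,
shared among several proteins, or "ambiguous N-terminal" — the special case
where the Met-retained N-terminal peptide of a canonical protein is also an
internal tryptic peptide of an N-terminally extended isoform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd
from pyteomics import parser as _pyt_parser

from apmsref.io import PeptideEvidence, ProteinRecord, ValidationError

#: Residues after which Met-aminopeptidase excises the initiator methionine.
MET_EXCISION_SECOND_RESIDUES = frozenset("ACGPSTV")

ACETYL_DELTA = 42

UNIQUE = "unique"
SHARED = "shared"
AMBIGUOUS_NTERM = "ambiguous_nterm"


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings (defaults match common search settings)."""

    max_missed_cleavages: int = 1
    min_length: int = 7
    cleave_after: frozenset = frozenset("KR")
    suppress_before_proline: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValidationError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")

    @property
    def rule(self) -> str:
        chars = "".join(sorted(self.cleave_after))
        if self.suppress_before_proline:
            return f"[{chars}](?!P)"
        return f"[{chars}]"


class DigestPeptide(NamedTuple):
    """A digest product with 1-based inclusive residue coordinates."""

    sequence: str
    start: int
    end: int


def tryptic_digest(sequence: str, params: DigestParams | None = None) -> list[DigestPeptide]:
    """Digest ``sequence``, returning peptides with residue coordinates.

    Peptides shorter than ``params.min_length`` are excluded; missed-cleavage
    concatenations up to ``params.max_missed_cleavages`` are included.
    Results are sorted by start coordinate, then end.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    params = params or DigestParams()
    seen: set[tuple[int, str]] = set()
    out: list[DigestPeptide] = []
    for start0, pep in _pyt_parser.icleave(
        sequence,
        params.rule,
        missed_cleavages=params.max_missed_cleavages,
        min_length=1,
    ):
        if len(pep) < params.min_length:
            continue
        key = (start0, pep)
        if key in seen:
            continue
        seen.add(key)
        out.append(DigestPeptide(pep, start0 + 1, start0 + len(pep)))
    out.sort(key=lambda p: (p.start, p.end))
    return out


@dataclass(frozen=True)
class PeptideForm:
    """An N-terminal peptide form: sequence, +42 flag and excision flag."""

    sequence: str
    nterm_mod_delta: int
    met_excised: bool


def nterm_processed_forms(
    record: ProteinRecord, params: DigestParams | None = None
) -> list[PeptideForm]:
    """Observable forms of a protein's N-terminal tryptic peptide.

    For a sequence starting with Met the first tryptic peptide can appear
    Met-retained or (if residue 2 permits excision) Met-excised, each with
    or without N-terminal acetylation (+42). Internal peptides are
    unaffected. Forms shorter than ``params.min_length`` are dropped.
    """
    params = params or DigestParams()
    if not record.sequence.startswith("M"):
        return []
    first = tryptic_digest(
        record.sequence,
        DigestParams(
            max_missed_cleavages=0,
            min_length=1,
            cleave_after=params.cleave_after,
            suppress_before_proline=params.suppress_before_proline,
        ),
    )[0]
    bases = [(first.sequence, False)]
    if len(record.sequence) > 1 and record.sequence[1] in MET_EXCISION_SECOND_RESIDUES:
        bases.append((first.sequence[1:], True))
    forms = [
        PeptideForm(seq, delta, excised)
        for seq, excised in bases
        for delta in (0, ACETYL_DELTA)
        if len(seq) >= params.min_length
    ]
    return forms


@dataclass(frozen=True)
class Classification:
    """Outcome of peptide-to-isoform assignment."""

    kind: str  # unique | shared | ambiguous_nterm
    protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValidationError("classification must name at least one protein")


def _strip_delta(peptide: str) -> tuple[str, int]:
    if peptide.startswith("42+"):
        return peptide[3:], ACETYL_DELTA
    return peptide, 0


def _occurrences(
    peptide: str, db: Sequence[ProteinRecord], params: DigestParams
) -> dict[str, set[str]]:
    """Map protein_id -> occurrence kinds of ``peptide`` honoring digestion.

    Kinds: ``nterm`` (tryptic peptide starting at residue 1), ``internal``
    (any other tryptic occurrence), ``nterm_excised`` (Met-excised
    N-terminal form).
    """
    loose = DigestParams(
        max_missed_cleavages=params.max_missed_cleavages,
        min_length=1,
        cleave_after=params.cleave_after,
        suppress_before_proline=params.suppress_before_proline,
    )
    occ: dict[str, set[str]] = {}
    for rec in db:
        kinds: set[str] = set()
        for dp in tryptic_digest(rec.sequence, loose):
            if dp.sequence == peptide:
                kinds.add("nterm" if dp.start == 1 else "internal")
        for form in nterm_processed_forms(rec, loose):
            if form.met_excised and form.sequence == peptide:
                kinds.add("nterm_excised")
        if kinds:
            occ[rec.protein_id] = kinds
    return occ


def classify_peptide(
    peptide: str,
    db: Sequence[ProteinRecord],
    isoform_groups: Mapping[str, Sequence[str]] | None = None,
    params: DigestParams | None = None,
) -> Classification:
    """Classify a peptide as unique, shared, or ambiguous N-terminal.

    A peptide is *unique* to an isoform iff, as a substring honoring
    tryptic digestion boundaries (or as a processed N-terminal form), it
    occurs in exactly one database sequence. Occurrences in two or more
    sequences make it *shared*, except the Met-retained N-terminal /
    internal-peptide coincidence between a canonical protein and its
    N-terminally extended isoform, which is flagged *ambiguous_nterm*.
    ``isoform_groups`` (parent -> variants) is accepted for interface
    symmetry with the report writer; the classification itself scans the
    whole database, so group membership never loosens uniqueness.
    """
    del isoform_groups  # uniqueness is database-wide by construction
    params = params or DigestParams()
    bare, _delta = _strip_delta(peptide)
    if not bare:
        raise ValidationError("empty peptide")
    occ = _occurrences(bare, db, params)
    if not occ:
        raise ValidationError(
            f"peptide {peptide!r} does not occur in any database sequence"
        )
    if len(occ) == 1:
        return Classification(UNIQUE, frozenset(occ))
    has_nterm_met = any("nterm" in kinds and bare.startswith("M") for kinds in occ.values())
    has_internal_only = any(kinds == {"internal"} for kinds in occ.values())
    if has_nterm_met and has_internal_only:
        return Classification(AMBIGUOUS_NTERM, frozenset(occ))
    return Classification(SHARED, frozenset(occ))


def tally_isoform_counts(
    evidence: Sequence[PeptideEvidence],
    classifications: Mapping[str, Classification],
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-isoform summed spectral counts of unique peptides.

    Returns ``(unique_tallies, unapportioned)``: unique peptide counts
    summed per protein, and shared/ambiguous totals reported separately —
    never apportioned among proteins. Keys of ``classifications`` are bare
    peptide sequences. Order of ``evidence`` does not affect the result.
    """
    unique: dict[str, int] = {}
    other: dict[str, int] = {SHARED: 0, AMBIGUOUS_NTERM: 0}
    for pep in evidence:
        cls = classifications.get(pep.peptide_sequence)
        if cls is None:
            continue
        if cls.kind == UNIQUE:
            (pid,) = cls.protein_ids
            unique[pid] = unique.get(pid, 0) + pep.total_count
        else:
            other[cls.kind] += pep.total_count
    return unique, other


def isoform_evidence_table(
    evidence: Sequence[PeptideEvidence],
    db: Sequence[ProteinRecord],
    isoform_groups: Mapping[str, Sequence[str]] | None = None,
    params: DigestParams | None = None,
) -> pd.DataFrame:
    """Build the peptide-level isoform evidence report.

    One row per peptide form: sequence, modification delta, classification,
    carrying protein(s), 1-based coordinates in the (first) carrying
    protein, and total spectral count.
    """
    params = params or DigestParams()
    by_id = {rec.protein_id: rec for rec in db}
    rows = []
    for pep in evidence:
        cls = classify_peptide(pep.peptide_sequence, db, isoform_groups, params)
        carrier = sorted(cls.protein_ids)[0]
        pos = by_id[carrier].sequence.find(pep.peptide_sequence)
        coords = (
            f"{pos + 1}-{pos + len(pep.peptide_sequence)}" if pos >= 0 else ""
        )
        rows.append(
            {
                "peptide_sequence": pep.peptide_sequence,
                "nterm_mod_delta": pep.nterm_mod_delta,
                "classification": cls.kind,
                "protein_ids": ";".join(sorted(cls.protein_ids)),
                "coordinates": coords,
                "total_spectra": pep.total_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_sequence",
            "nterm_mod_delta",
            "classification",
            "protein_ids",
            "coordinates",
            "total_spectra",
        ],
    )
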