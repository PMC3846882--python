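"""Data model, readers/writers and validation for spectral-count experiments.

The pipeline's central objects are a protein sequence database (FASTA), an
experiment design table mapping LC-MS/MS runs to conditions (bait
purification, mock control, whole-cell lysate), a run x protein spectral
count matrix, and optional peptide-level evidence. All tabular formats are
UTF-8 TSV with a header row; missing cells in count tables mean zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Experiment design condition labels.
CONDITION_BAIT = "bait"
CONDITION_CONTROL = "control"
CONDITION_WCL = "wcl"
CONDITIONS = (CONDITION_BAIT, CONDITION_CONTROL, CONDITION_WCL)


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry.

    ``length`` (the residue count) is the ``L`` that normalises spectral
    counts in NSAF.
    """

    protein_id: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def index_records(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Map protein_id -> record, rejecting duplicate accessions."""
    out: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.protein_id in out:
            raise ValidationError(f"duplicate protein_id {rec.protein_id!r}")
        out[rec.protein_id] = rec
    return out


def protein_lengths(records: Iterable[ProteinRecord]) -> pd.Series:
    idx = index_records(records)
    return pd.Series({pid: rec.length for pid, rec in idx.items()}, dtype=float)


class ExperimentDesign:
    """Run -> condition/bait/replicate assignment.

    Backed by a DataFrame with columns ``run_id, condition, bait_id,
    replicate``. Bait runs carry the bait's protein_id; control and
    whole-cell-lysate (WCL) runs leave ``bait_id`` empty.
    """

    COLUMNS = ("run_id", "condition", "bait_id", "replicate")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValidationError(f"design table missing columns {sorted(missing)}")
        table = table[list(self.COLUMNS)]
        table["run_id"] = table["run_id"].astype(str)
        table["bait_id"] = table["bait_id"].fillna("").astype(str)
        if table["run_id"].duplicated().any():
            dup = table.loc[table["run_id"].duplicated(), "run_id"].iloc[0]
            raise ValidationError(f"duplicate run_id {dup!r} in design")
        bad_cond = set(table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown condition(s) {sorted(bad_cond)}; expected {CONDITIONS}"
            )
        reps = pd.to_numeric(table["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
            raise ValidationError("replicate must be a positive integer")
        table["replicate"] = reps.astype(int)
        is_bait = table["condition"] == CONDITION_BAIT
        if (table.loc[is_bait, "bait_id"] == "").any():
            raise ValidationError("bait runs must name a bait_id")
        if (table.loc[~is_bait, "bait_id"] != "").any():
            raise ValidationError("control/WCL runs must not name a bait_id")
        pairs = table.loc[is_bait, ["bait_id", "replicate"]]
        if pairs.duplicated().any():
            raise ValidationError("(bait_id, replicate) pairs must be unique")
        self.table = table.reset_index(drop=True)

    @property
    def run_ids(self) -> list[str]:
        return list(self.table["run_id"])

    @property
    def baits(self) -> list[str]:
        is_bait = self.table["condition"] == CONDITION_BAIT
        return list(dict.fromkeys(self.table.loc[is_bait, "bait_id"]))

    def bait_runs(self, bait_id: str) -> list[str]:
        """Run ids for one bait, ordered by replicate index."""
        sel = (self.table["condition"] == CONDITION_BAIT) & (
            self.table["bait_id"] == bait_id
        )
        if not sel.any():
            raise ValidationError(f"no bait runs for {bait_id!r}")
        return list(self.table.loc[sel].sort_values("replicate")["run_id"])

    @property
    def control_runs(self) -> list[str]:
        sel = self.table["condition"] == CONDITION_CONTROL
        return list(self.table.loc[sel, "run_id"])

    @property
    def wcl_runs(self) -> list[str]:
        sel = self.table["condition"] == CONDITION_WCL
        return list(self.table.loc[sel, "run_id"])


@dataclass
class SpectralCountMatrix:
    """Run x protein spectral counts (non-negative integers).

    Rows are run_ids appearing in the design; columns are protein accessions.
    """

    counts: pd.DataFrame
    design: ExperimentDesign | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if arr.size:
            flat = pd.to_numeric(pd.Series(arr.ravel()), errors="coerce")
            if flat.isna().any():
                raise ValidationError("non-numeric spectral count")
            if (flat < 0).any():
                raise ValidationError("negative spectral count")
            if (flat != flat.round()).any():
                raise ValidationError("non-integer spectral count")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "run_id"
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.columns.name = None
        if self.design is not None:
            extra = set(self.counts.index) - set(self.design.run_ids)
            if extra:
                raise ValidationError(
                    f"run(s) {sorted(extra)} absent from experiment design"
                )

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.columns)

    def run_depths(self) -> pd.Series:
        """Total spectra per run (column sums of the transposed table)."""
        return self.counts.sum(axis=1).astype(float)

    def validate_against_db(self, records: Sequence[ProteinRecord]) -> None:
        known = {r.protein_id for r in records}
        orphans = set(self.counts.columns) - known
        if orphans:
            raise ValidationError(
                f"count matrix column(s) without a protein record: {sorted(orphans)[:5]}"
            )


@dataclass(frozen=True)
class PeptideEvidence:
    """One observed peptide form with per-run spectral counts.

    ``nterm_mod_delta`` is the nominal N-terminal modification mass in Da
    (0 for unmodified, 42 for acetylation).
    """

    peptide_sequence: str
    nterm_mod_delta: int
    assigned_protein_ids: frozenset[str]
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValidationError("empty peptide sequence")
        if self.nterm_mod_delta not in (0, 42):
            raise ValidationError("nterm_mod_delta must be 0 or 42")
        if not self.assigned_protein_ids:
            raise ValidationError(
                f"peptide {self.peptide_sequence}: no assigned proteins"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(
                f"peptide {self.peptide_sequence}: negative count"
            )

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered set of protein_ids declared to form the known core complex."""

    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError("reference set has duplicate members")
        if len(self.member_ids) < 2:
            raise ValidationError("reference set needs at least 2 members")

    def validate_against_db(self, records: Sequence[ProteinRecord]) -> None:
        known = {r.protein_id for r in records}
        missing = set(self.member_ids) - known
        if missing:
            raise ValidationError(
                f"reference member(s) absent from database: {sorted(missing)}"
            )

    def __iter__(self):
        return iter(self.member_ids)

    def __contains__(self, item: str) -> bool:
        return item in self.member_ids


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records.

    Headers are ``>protein_id [gene_symbol ...]``; the first description
    token is taken as the gene symbol (falling back to the accession).
    Parse errors name the offending line; duplicate accessions are rejected.

    A line-tracking reader is used (rather than a generic FASTA library)
    so that malformed input can be reported by line number.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: str | None = None
    seq_parts: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        tokens = header.split()
        pid = tokens[0]
        gene = tokens[1] if len(tokens) > 1 else pid
        seq = "".join(seq_parts)
        if not seq:
            raise ParseError(f"{path}:{header_line}: entry {pid!r} has no sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ParseError(
                f"{path}:{header_line}: entry {pid!r} contains "
                f"non-amino-acid characters {sorted(bad)}"
            )
        records.append(ProteinRecord(pid, gene, seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                seq_parts = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                seq_parts.append(line.upper())
        flush()

    index_records(records)  # raises on duplicate ids
    if not records:
        logger.warning("FASTA file %s contained no entries", path)
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} {rec.gene_symbol}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table["replicate"] = pd.to_numeric(table["replicate"], errors="coerce")
    table.loc[table["bait_id"] == "", "bait_id"] = ""
    return ExperimentDesign(table)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, design: ExperimentDesign) -> SpectralCountMatrix:
    """Read a run x protein TSV; blank cells count as zero."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table = table.fillna(0)
    table.index = table.index.astype(str)
    return SpectralCountMatrix(table, design=design)


def write_count_matrix(matrix: SpectralCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "run_id"
    out.to_csv(path, sep="\t")


def read_reference_set(path: str | Path) -> ReferenceSet:
    """One member accession per line (or first TSV column); '#' comments."""
    members: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members.append(line.split("\t")[0])
    if members and members[0].lower() in {"protein_id", "member_id", "accession"}:
        members = members[1:]
    return ReferenceSet(tuple(members))


def write_reference_set(reference: ReferenceSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\n")
        for member in reference:
            fh.write(member + "\n")


PEPTIDE_META_COLUMNS = ("peptide_sequence", "nterm_mod_delta", "assigned_protein_ids")


def read_peptide_table(path: str | Path) -> list[PeptideEvidence]:
    """Read peptide evidence: meta columns then one count column per run."""
    table = pd.read_csv(path, sep="\t", dtype={"peptide_sequence": str})
    missing = set(PEPTIDE_META_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"peptide table missing columns {sorted(missing)}")
    run_cols = [c for c in table.columns if c not in PEPTIDE_META_COLUMNS]
    out: list[PeptideEvidence] = []
    for _, row in table.iterrows():
        counts = {r: int(row[r]) for r in run_cols if not pd.isna(row[r])}
        out.append(
            PeptideEvidence(
                peptide_sequence=row["peptide_sequence"],
                nterm_mod_delta=int(row["nterm_mod_delta"]),
                assigned_protein_ids=frozenset(
                    str(row["assigned_protein_ids"]).split(";")
                ),
                counts=counts,
            )
        )
    return out


def write_peptide_table(
    peptides: Sequence[PeptideEvidence], path: str | Path, run_ids: Sequence[str]
) -> None:
    rows = []
    for pep in peptides:
        row = {
            "peptide_sequence": pep.peptide_sequence,
            "nterm_mod_delta": pep.nterm_mod_delta,
            "assigned_protein_ids": ";".join(sorted(pep.assigned_protein_ids)),
        }
        for run in run_ids:
            row[run] = pep.counts.get(run, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Identification filters
# ---------------------------------------------------------------------------

def apply_identification_filters(
    matrix: SpectralCountMatrix,
    design: ExperimentDesign,
    peptides: Sequence[PeptideEvidence] | None = None,
    *,
    min_peptide_length: int = 7,
    min_bait_total: int = 2,
    require_replicate_presence: bool = False,
) -> SpectralCountMatrix:
    """Apply the standard identification filters to a count matrix.

    Two rules, in order:

    1. When peptide evidence is supplied, peptides shorter than
       ``min_peptide_length`` residues are discarded and the counts of every
       protein covered by peptide evidence are re-tallied from the retained
       peptides (shared peptides contribute to each assigned protein).
    2. Within each bait's replicate series, a protein whose total spectral
       count is below ``min_bait_total`` is removed for that bait (its
       counts in those runs are zeroed). With
       ``require_replicate_presence`` the rule instead demands detection in
       at least ``min_bait_total`` replicates.

    The filter is idempotent, never increases a count, and never adds a
    protein. Control and WCL runs are untouched by rule 2.
    """
    counts = matrix.counts.copy()

    if peptides is not None:
        covered = sorted(set().union(*(p.assigned_protein_ids for p in peptides))) if peptides else []
        covered = [p for p in covered if p in counts.columns]
        if covered:
            counts.loc[:, covered] = 0
            kept = 0
            for pep in peptides:
                if len(pep.peptide_sequence) < min_peptide_length:
                    continue
                kept += 1
                for pid in pep.assigned_protein_ids:
                    if pid not in counts.columns:
                        continue
                    for run, c in pep.counts.items():
                        if run in counts.index:
                            counts.loc[run, pid] += int(c)
            logger.info(
                "peptide length filter: kept %d/%d peptides (min length %d)",
                kept, len(peptides), min_peptide_length,
            )

    removed_pairs = 0
    for bait in design.baits:
        runs = [r for r in design.bait_runs(bait) if r in counts.index]
        if not runs:
            continue
        block = counts.loc[runs]
        if require_replicate_presence:
            weak = (block > 0).sum(axis=0) < min_bait_total
        else:
            weak = block.sum(axis=0) < min_bait_total
        weak &= block.sum(axis=0) > 0  # only log/zero proteins actually seen
        if weak.any():
            removed_pairs += int(weak.sum())
            counts.loc[runs, weak[weak].index] = 0
            logger.info(
                "bait %s: removed %d protein(s) below the spectra threshold",
                bait, int(weak.sum()),
            )

    nonzero = counts.sum(axis=0) > 0
    dropped = int((~nonzero).sum())
    counts = counts.loc[:, nonzero]
    if dropped:
        logger.info("dropped %d all-zero protein column(s) after filtering", dropped)
    if counts.shape[1] == 0:
        logger.warning("identification filters removed every protein")
    return SpectralCountMatrix(counts, design=matrix.design)


def collapse_protein_groups(
    peptides: Sequence[PeptideEvidence],
) -> dict[str, str]:
    """Greedy parsimony collapse of indistinguishable accessions.

    Proteins whose peptide evidence sets are identical are merged into one
    group represented by the lexicographically smallest accession. Returns
    a protein_id -> representative map (identity for unaffected proteins).
    """
    pepsets: dict[str, frozenset[str]] = {}
    for pep in peptides:
        for pid in pep.assigned_protein_ids:
            pepsets.setdefault(pid, frozenset())
    for pep in peptides:
        for pid in pep.assigned_protein_ids:
            pepsets[pid] = pepsets[pid] | {pep.peptide_sequence}
    groups: dict[frozenset[str], list[str]] = {}
    for pid, s in pepsets.items():
        groups.setdefault(s, []).append(pid)
    mapping: dict[str, str] = {}
    for members in groups.values():
        rep = min(members)
        for pid in members:
            mapping[pid] = rep
    return mapping
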