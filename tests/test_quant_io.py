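"""Readers, validation and identification filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmsref.io import (
    ExperimentDesign,
    ParseError,
    PeptideEvidence,
    ProteinRecord,
    ReferenceSet,
    SpectralCountMatrix,
    ValidationError,
    apply_identification_filters,
    collapse_protein_groups,
    read_count_matrix,
    read_fasta,
    write_count_matrix,
    write_fasta,
)


# ---------------------------------------------------------------- FASTA


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(">P1 x\nMKR\n")
    records = read_fasta(p)
    assert len(records) == 1
    assert records[0].protein_id == "P1"
    assert records[0].gene_symbol == "x"
    assert records[0].length == 3


def test_read_fasta_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with caplog.at_level("WARNING"):
        assert read_fasta(p) == []
    assert any("no entries" in r.message for r in caplog.records)


def test_read_fasta_duplicate_id_rejected(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">P1 a\nMKR\n>P1 b\nMKR\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_fasta(p)


def test_read_fasta_bad_residue_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">P1 a\nMKR\n>P2 b\nMK1R\n")
    with pytest.raises(ParseError, match="bad.fasta:3"):
        read_fasta(p)


def test_fasta_round_trip(tmp_path, toy_isoform_db):
    p = tmp_path / "rt.fasta"
    write_fasta(toy_isoform_db, p)
    back = read_fasta(p)
    assert [(r.protein_id, r.sequence) for r in back] == [
        (r.protein_id, r.sequence) for r in toy_isoform_db
    ]


def test_protein_record_rejects_empty_and_nonresidue():
    with pytest.raises(ValidationError):
        ProteinRecord("P1", "P1", "")
    with pytest.raises(ValidationError):
        ProteinRecord("P1", "P1", "MKBZ")


# ------------------------------------------------------------ count matrix


def _write_counts(tmp_path, body: str):
    p = tmp_path / "counts.tsv"
    p.write_text("run_id\tP1\tP2\tP3\n" + body)
    return p


def test_read_count_matrix_blank_cell_is_zero(tmp_path, small_design):
    p = _write_counts(tmp_path, "b1_r1\t3\t\t1\nctrl\t0\t2\t5\n")
    m = read_count_matrix(p, small_design)
    assert m.counts.loc["b1_r1", "P2"] == 0
    assert m.counts.loc["ctrl", "P3"] == 5


@pytest.mark.parametrize("bad", ["-1", "3.5"])
def test_read_count_matrix_rejects_invalid_counts(tmp_path, small_design, bad):
    p = _write_counts(tmp_path, f"b1_r1\t3\t{bad}\t1\n")
    with pytest.raises(ValidationError):
        read_count_matrix(p, small_design)


def test_read_count_matrix_unknown_run_rejected(tmp_path, small_design):
    p = _write_counts(tmp_path, "mystery_run\t1\t2\t3\n")
    with pytest.raises(ValidationError, match="mystery_run"):
        read_count_matrix(p, small_design)


def test_count_matrix_round_trip(tmp_path, small_design):
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(5, 4)),
        index=["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
        columns=[f"P{i}" for i in range(1, 5)],
    )
    m = SpectralCountMatrix(counts, design=small_design)
    p = tmp_path / "rt.tsv"
    write_count_matrix(m, p)
    back = read_count_matrix(p, small_design)
    pd.testing.assert_frame_equal(back.counts, m.counts)


# ------------------------------------------------------------ design/reference


def test_design_invariants():
    base = pd.DataFrame(
        {
            "run_id": ["a", "b"],
            "condition": ["bait", "bait"],
            "bait_id": ["P1", "P1"],
            "replicate": [1, 1],
        }
    )
    with pytest.raises(ValidationError, match="unique"):
        ExperimentDesign(base)
    ok = base.assign(replicate=[1, 2])
    assert ExperimentDesign(ok).bait_runs("P1") == ["a", "b"]


def test_reference_set_needs_two_members_in_db(toy_isoform_db):
    with pytest.raises(ValidationError):
        ReferenceSet(("only",))
    ref = ReferenceSet(("CANOA", "GHOST"))
    with pytest.raises(ValidationError, match="GHOST"):
        ref.validate_against_db(toy_isoform_db)


# ------------------------------------------------------------ filters


def _matrix(small_design, rows):
    counts = pd.DataFrame(
        rows,
        index=["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
        columns=["P1", "P2", "P3"],
    )
    return SpectralCountMatrix(counts, design=small_design)


def test_filter_removes_single_spectrum_protein_per_bait(small_design):
    # P2 has exactly 1 spectrum over the bait series -> removed for that bait
    m = _matrix(
        small_design,
        [[5, 1, 0], [5, 0, 1], [5, 0, 1], [0, 3, 0], [9, 9, 9]],
    )
    out = apply_identification_filters(m, small_design)
    assert out.counts.loc[["b1_r1", "b1_r2", "b1_r3"], "P2"].sum() == 0
    # control/WCL counts untouched
    assert out.counts.loc["ctrl", "P2"] == 3
    # boundary: P3 total is exactly 2 -> retained
    assert out.counts.loc[["b1_r1", "b1_r2", "b1_r3"], "P3"].sum() == 2


def test_filter_replicate_presence_mode(small_design):
    # P3 seen in 2 replicates -> kept; P2's 2 spectra sit in one replicate
    m = _matrix(
        small_design,
        [[5, 2, 1], [5, 0, 1], [5, 0, 0], [0, 0, 0], [9, 9, 9]],
    )
    out = apply_identification_filters(
        m, small_design, require_replicate_presence=True
    )
    assert out.counts.loc[["b1_r1", "b1_r2", "b1_r3"], "P2"].sum() == 0
    assert out.counts.loc[["b1_r1", "b1_r2", "b1_r3"], "P3"].sum() == 2


def test_short_peptides_dropped_before_tally(small_design):
    peptides = [
        PeptideEvidence("ANNDAVK", 0, frozenset({"P1"}), {"b1_r1": 4, "b1_r2": 4}),
        PeptideEvidence("NNDAVK", 0, frozenset({"P1"}), {"b1_r1": 50}),
    ]
    m = _matrix(
        small_design,
        [[54, 5, 0], [4, 5, 0], [0, 5, 0], [0, 0, 0], [9, 9, 9]],
    )
    out = apply_identification_filters(m, small_design, peptides)
    # P1 re-tallied from the retained 7-mer only
    assert out.counts.loc["b1_r1", "P1"] == 4
    assert out.counts.loc["b1_r2", "P1"] == 4


def test_filter_idempotent_and_monotone(small_design):
    rng = np.random.default_rng(11)
    for _ in range(10):
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(5, 3)),
            index=["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
            columns=["P1", "P2", "P3"],
        )
        m = SpectralCountMatrix(counts, design=small_design)
        once = apply_identification_filters(m, small_design)
        twice = apply_identification_filters(once, small_design)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        # never increases a count, never adds a protein
        assert set(once.protein_ids) <= set(m.protein_ids)
        aligned = once.counts.reindex(columns=m.counts.columns, fill_value=0)
        assert (aligned.to_numpy() <= m.counts.to_numpy()).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(0, 4), min_size=3, max_size=3),
        min_size=5,
        max_size=5,
    )
)
def test_filter_idempotence_property(rows):
    design = ExperimentDesign(
        pd.DataFrame(
            {
                "run_id": ["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
                "condition": ["bait", "bait", "bait", "control", "wcl"],
                "bait_id": ["P1", "P1", "P1", "", ""],
                "replicate": [1, 2, 3, 1, 1],
            }
        )
    )
    counts = pd.DataFrame(
        rows,
        index=["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
        columns=["P1", "P2", "P3"],
    )
    m = SpectralCountMatrix(counts, design=design)
    once = apply_identification_filters(m, design)
    twice = apply_identification_filters(once, design)
    pd.testing.assert_frame_equal(once.counts, twice.counts)


def test_collapse_protein_groups_merges_identical_peptide_sets():
    peps = [
        PeptideEvidence("AAAAAAK", 0, frozenset({"P2", "P1"}), {}),
        PeptideEvidence("CCCCCCK", 0, frozenset({"P1", "P2"}), {}),
        PeptideEvidence("DDDDDDK", 0, frozenset({"P3"}), {}),
    ]
    mapping = collapse_protein_groups(peps)
    assert mapping["P1"] == "P1"
    assert mapping["P2"] == "P1"
    assert mapping["P3"] == "P3"
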