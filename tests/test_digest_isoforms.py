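"""Tryptic digestion, N-terminal processing and isoform classification."""

import numpy as np
import pytest

from apmsref.digest import (
    AMBIGUOUS_NTERM,
    SHARED,
    UNIQUE,
    Classification,
    DigestParams,
    classify_peptide,
    isoform_evidence_table,
    nterm_processed_forms,
    tally_isoform_counts,
    tryptic_digest,
)
from apmsref.io import PeptideEvidence, ProteinRecord, ValidationError

from oracles import brute_force_classify, brute_force_digest

AA = list("ACDEFGHIKLMNPQRSTVWY")


# --------------------------------------------------------------- digestion


def test_single_internal_cut():
    peps = tryptic_digest("MKAAAAAAR", DigestParams(max_missed_cleavages=0))
    assert peps == [("AAAAAAR", 3, 9)]


def test_kp_bond_not_cleaved():
    # an internal K-P survives digestion, as in the observed N-terminal
    # peptide PMYQVKPYHGGGAPLR spanning an uncut K-P
    seq = "MPMYQVKPYHGGGAPLRGGGGGGK"
    peps = {p.sequence for p in tryptic_digest(seq, DigestParams(max_missed_cleavages=0, min_length=1))}
    assert "MPMYQVKPYHGGGAPLR" in peps
    assert not any(p.endswith("QVK") for p in peps)


def test_missed_cleavage_products_present():
    peps = tryptic_digest("AAAKBBBKCCCC".replace("B", "G"), DigestParams(max_missed_cleavages=1, min_length=1))
    seqs = {p.sequence for p in peps}
    assert {"AAAK", "GGGK", "CCCC", "AAAKGGGK", "GGGKCCCC"} <= seqs


@pytest.mark.parametrize("missed", [0, 1, 2])
def test_digest_matches_brute_force_oracle(missed):
    rng = np.random.default_rng(42)
    for _ in range(50):
        seq = "".join(rng.choice(AA, size=300))
        got = {
            (p.sequence, p.start, p.end)
            for p in tryptic_digest(seq, DigestParams(max_missed_cleavages=missed))
        }
        expected = brute_force_digest(seq, max_missed=missed, min_length=7)
        assert got == expected


def test_zero_missed_digest_reconstructs_parent():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(AA, size=400))
    peps = tryptic_digest(seq, DigestParams(max_missed_cleavages=0, min_length=1))
    assert "".join(p.sequence for p in sorted(peps, key=lambda p: p.start)) == seq


# ------------------------------------------------------- N-terminal forms


def test_nterm_forms_with_excisable_second_residue():
    rec = ProteinRecord("P1", "P1", "MANNDAVLKGGGGGGGR")
    forms = {(f.sequence, f.nterm_mod_delta) for f in nterm_processed_forms(rec, DigestParams())}
    assert forms == {
        ("MANNDAVLK", 0),
        ("MANNDAVLK", 42),
        ("ANNDAVLK", 0),
        ("ANNDAVLK", 42),
    }


def test_no_met_excision_after_bulky_residue():
    rec = ProteinRecord("P1", "P1", "MWNNDAVLKGGGGGGGR")
    forms = nterm_processed_forms(rec, DigestParams())
    assert all(not f.met_excised for f in forms)
    assert {f.nterm_mod_delta for f in forms} == {0, 42}


def test_mod_deltas_are_only_0_or_42(default_sim):
    _, records, *_ = default_sim
    for rec in records[:20]:
        for f in nterm_processed_forms(rec, DigestParams()):
            assert f.nterm_mod_delta in (0, 42)


# ---------------------------------------------------------- classification


def test_junction_peptide_unique_to_deletion_variant(toy_isoform_db):
    cls = classify_peptide("SYGPAPGAGHVQDYGALK", toy_isoform_db)
    assert cls.kind == UNIQUE
    assert cls.protein_ids == frozenset({"VARB"})
    cls_full = classify_peptide("SYGPAPGAGHVQEESNLSLQALESR", toy_isoform_db)
    assert cls_full.kind == UNIQUE
    assert cls_full.protein_ids == frozenset({"CANOB"})


def test_met_retained_nterm_peptide_is_ambiguous(toy_isoform_db):
    cls = classify_peptide("MANNDAVLK", toy_isoform_db)
    assert cls.kind == AMBIGUOUS_NTERM
    assert cls.protein_ids == frozenset({"CANOA", "EXTA"})


def test_met_excised_form_unique_to_canonical(toy_isoform_db):
    cls = classify_peptide("ANNDAVLK", toy_isoform_db)
    assert cls.kind == UNIQUE
    assert cls.protein_ids == frozenset({"CANOA"})


def test_acetylated_extension_peptide_unique_to_variant(toy_isoform_db):
    cls = classify_peptide("42+MLPAVAVSEPVVLR", toy_isoform_db)
    assert cls.kind == UNIQUE
    assert cls.protein_ids == frozenset({"EXTA"})


def test_shared_nterm_region_is_shared(toy_isoform_db):
    cls = classify_peptide("PMYQVKPYHGGGAPLR", toy_isoform_db)
    assert cls.kind == SHARED
    assert cls.protein_ids == frozenset({"CANOB", "VARB"})


def test_unknown_peptide_raises_naming_it(toy_isoform_db):
    with pytest.raises(ValidationError, match="WWWWWWW"):
        classify_peptide("WWWWWWW", toy_isoform_db)


def test_classification_matches_substring_oracle(default_sim):
    """Agreement with the naive all-substring oracle on a generated db."""
    _, records, truth, *_ = default_sim
    by_id = {r.protein_id: r.sequence for r in records}
    iso_ids = [p for pair in truth.isoform_groups.items() for p in (pair[0], *pair[1])]
    probes = []
    for pid in iso_ids:
        digest = tryptic_digest(by_id[pid], DigestParams())
        probes.extend(p.sequence for p in digest[:15])
        rec = next(r for r in records if r.protein_id == pid)
        probes.extend(f.sequence for f in nterm_processed_forms(rec, DigestParams()))
    for pep in sorted(set(probes)):
        expected = brute_force_classify(pep, by_id, max_missed=1)
        assert expected is not None
        got = classify_peptide(pep, records)
        assert (got.kind, got.protein_ids) == expected, pep


def test_no_peptide_unique_to_two_isoforms(toy_isoform_db):
    seen = {}
    for rec in toy_isoform_db:
        for p in tryptic_digest(rec.sequence, DigestParams()):
            cls = classify_peptide(p.sequence, toy_isoform_db)
            if cls.kind == UNIQUE:
                (owner,) = cls.protein_ids
                assert seen.setdefault(p.sequence, owner) == owner


# ----------------------------------------------------------------- tallies


def _ev(seq, counts, pids=("X",)):
    return PeptideEvidence(seq, 0, frozenset(pids), counts)


def test_tally_unique_and_unapportioned():
    classifications = {
        "AAAAAAK": Classification(UNIQUE, frozenset({"ISO1"})),
        "CCCCCCK": Classification(UNIQUE, frozenset({"ISO2"})),
        "DDDDDDK": Classification(SHARED, frozenset({"ISO1", "ISO2"})),
        "MEEEEEK": Classification(AMBIGUOUS_NTERM, frozenset({"ISO1", "ISO2"})),
    }
    evidence = [
        _ev("AAAAAAK", {"r1": 2, "r2": 1}),
        _ev("CCCCCCK", {"r1": 5}),
        _ev("DDDDDDK", {"r1": 7}),
        _ev("MEEEEEK", {"r2": 4}),
    ]
    unique, other = tally_isoform_counts(evidence, classifications)
    assert unique == {"ISO1": 3, "ISO2": 5}
    assert other == {SHARED: 7, AMBIGUOUS_NTERM: 4}
    # permutation invariance
    unique_r, other_r = tally_isoform_counts(list(reversed(evidence)), classifications)
    assert (unique_r, other_r) == (unique, other)


def test_tally_no_unique_peptides():
    classifications = {"DDDDDDK": Classification(SHARED, frozenset({"A", "B"}))}
    unique, other = tally_isoform_counts([_ev("DDDDDDK", {"r1": 3})], classifications)
    assert unique == {}
    assert other[SHARED] == 3


def test_isoform_evidence_table_columns(toy_isoform_db):
    evidence = [
        PeptideEvidence("SYGPAPGAGHVQDYGALK", 0, frozenset({"VARB"}), {"r1": 5}),
        PeptideEvidence("MANNDAVLK", 0, frozenset({"CANOA", "EXTA"}), {"r1": 2}),
    ]
    table = isoform_evidence_table(evidence, toy_isoform_db)
    assert list(table["classification"]) == [UNIQUE, AMBIGUOUS_NTERM]
    row = table.iloc[0]
    assert row["coordinates"] == "18-35"  # 1-based inclusive in VARB
    assert row["total_spectra"] == 5
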