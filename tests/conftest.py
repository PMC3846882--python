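import pandas as pd
import pytest

from apmsref.io import ExperimentDesign, ProteinRecord
from apmsref.simulate import SimConfig, generate_protein_db, simulate_apms_counts


def make_toy_isoform_db() -> list[ProteinRecord]:
    """Two isoform pairs mirroring the canonical motivating cases.

    Pair A: canonical protein vs an N-terminally extended variant (the
    canonical's Met-retained N-terminal peptide recurs internally in the
    variant). Pair B: canonical vs an internal-deletion variant whose
    junction-spanning tryptic peptide occurs nowhere else; the shared
    N-terminal region contains an uncleaved K-P bond.
    """
    canon_a = "MANNDAVLK" + "LLEGSGSSHVDR" + "TTTTTTYGGGGGK" + "AVININDEER"
    ext_a = "MLPAVAVSEPVVLR" + "GSTAGSDLSK" + canon_a
    canon_b = (
        "MPMYQVKPYHGGGAPLR"
        + "SYGPAPGAGHVQ"
        + "EESNLSLQALESR"
        + "DYGALK"
        + "WFEEHGSNAVTR"
    )
    var_b = "MPMYQVKPYHGGGAPLR" + "SYGPAPGAGHVQ" + "DYGALK" + "WFEEHGSNAVTR"
    return [
        ProteinRecord("CANOA", "CANOA", canon_a),
        ProteinRecord("EXTA", "EXTA", ext_a),
        ProteinRecord("CANOB", "CANOB", canon_b),
        ProteinRecord("VARB", "VARB", var_b),
    ]


@pytest.fixture(scope="session")
def toy_isoform_db():
    return make_toy_isoform_db()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic experiment (seed 1), shared read-only."""
    cfg = SimConfig(seed=1)
    records, truth = generate_protein_db(cfg)
    matrix, design = simulate_apms_counts(records, truth, cfg)
    return cfg, records, truth, matrix, design


@pytest.fixture()
def small_design():
    return ExperimentDesign(
        pd.DataFrame(
            {
                "run_id": ["b1_r1", "b1_r2", "b1_r3", "ctrl", "wcl"],
                "condition": ["bait", "bait", "bait", "control", "wcl"],
                "bait_id": ["P1", "P1", "P1", "", ""],
                "replicate": [1, 2, 3, 1, 1],
            }
        )
    )
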