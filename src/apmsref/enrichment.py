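"""NSAF abundance profiles and relative enrichment factors (REF).

NSAF (normalised spectral abundance factor) of protein *i* in a run is
``(SpC_i / L_i) / sum_j (SpC_j / L_j)`` with ``SpC`` the spectral count and
``L`` the protein length in residues; every profile sums to one.

The relative enrichment factor compares a prey's purification-to-lysate
abundance ratio against the known core complex: each protein's AP-MS NSAF
is divided by its whole-cell-lysate NSAF, and the quotient is normalised by
the mean quotient of the reference-set members excluding the bait. By
construction the mean REF over the non-bait reference members is exactly 1,
so values near 1 mark complex-like enrichment; overexpressed baits score
well above 1, and sticky contaminants well below.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from apmsref.io import (
    ExperimentDesign,
    ReferenceSet,
    SpectralCountMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MEMBER_THRESHOLD = 0.3
DEFAULT_REPORT_THRESHOLD = 0.1


def compute_nsaf(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """NSAF profile for one run (or pooled condition).

    ``counts`` are per-protein spectral counts, ``lengths`` per-protein
    residue counts covering at least the counted proteins. The returned
    profile sums to 1; zero-count proteins get NSAF 0.
    """
    counts = counts.astype(float)
    if (counts < 0).any():
        raise ValidationError("negative spectral count in NSAF input")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"no length for protein(s) {list(missing)[:5]}")
    L = lengths.loc[counts.index].astype(float)
    if (L <= 0).any():
        raise ValidationError("protein lengths must be positive")
    saf = counts / L
    total = saf.sum()
    if total <= 0:
        raise ValidationError("cannot compute NSAF from all-zero counts")
    return saf / total


def condition_profile(
    matrix: SpectralCountMatrix,
    run_ids: list[str],
    lengths: pd.Series,
    *,
    mode: str = "replicate_mean",
) -> pd.Series:
    """Condition-level NSAF across replicate runs.

    ``replicate_mean`` (default) averages the per-run NSAF profiles
    arithmetically; ``pooled`` sums counts across runs before normalising.
    Either way the result sums to 1.
    """
    runs = [r for r in run_ids if r in matrix.counts.index]
    if not runs:
        raise ValidationError(f"none of the runs {run_ids} are in the count matrix")
    if mode == "pooled":
        return compute_nsaf(matrix.counts.loc[runs].sum(axis=0), lengths)
    if mode != "replicate_mean":
        raise ValidationError(f"unknown profile mode {mode!r}")
    profiles = [compute_nsaf(matrix.counts.loc[r], lengths) for r in runs]
    return sum(profiles) / len(profiles)


def compute_quotients(
    ap_profile: pd.Series, wcl_profile: pd.Series
) -> pd.Series:
    """Per-protein NSAF quotient AP / WCL.

    Defined only for proteins observed in the AP profile whose WCL NSAF is
    positive; proteins absent from the WCL are flagged and excluded (their
    enrichment is indeterminate, not infinite).
    """
    ap = ap_profile[ap_profile > 0]
    wcl = wcl_profile.reindex(ap.index).fillna(0.0)
    undefined = list(ap.index[wcl <= 0])
    if undefined:
        logger.info(
            "%d protein(s) absent from WCL excluded from enrichment: %s%s",
            len(undefined), undefined[:5], "..." if len(undefined) > 5 else "",
        )
    defined = wcl > 0
    return ap[defined] / wcl[defined]


def compute_ref(
    quotients: pd.Series,
    reference: ReferenceSet,
    bait_id: str,
) -> pd.DataFrame:
    """Normalise quotients by the non-bait reference-set mean.

    Returns a frame indexed by prey with columns ``quotient``, ``ref`` and
    ``in_reference_set``. The bait's own record is reported but never
    enters the normalising mean, so the mean REF over the non-bait
    reference members present is exactly 1.
    """
    effective = [m for m in reference if m != bait_id and m in quotients.index]
    if not effective:
        raise ValidationError(
            f"no non-bait reference member has a defined quotient for bait {bait_id!r}"
        )
    norm = float(quotients.loc[effective].mean())
    if norm <= 0:
        raise ValidationError("reference-set mean quotient must be positive")
    out = pd.DataFrame(
        {
            "quotient": quotients,
            "ref": quotients / norm,
            "in_reference_set": [p in reference for p in quotients.index],
        }
    )
    out.index.name = "prey_id"
    return out


def bait_ref_tables(
    matrix: SpectralCountMatrix,
    design: ExperimentDesign,
    lengths: pd.Series,
    reference: ReferenceSet,
    *,
    profile_mode: str = "replicate_mean",
) -> dict[str, pd.DataFrame]:
    """REF table per bait from a filtered count matrix.

    The AP-side profile is the replicate-mean NSAF of the bait's runs; the
    WCL profile averages the (usually single) WCL run(s).
    """
    if not design.wcl_runs:
        raise ValidationError("enrichment analysis requires a WCL run")
    wcl = condition_profile(matrix, design.wcl_runs, lengths, mode=profile_mode)
    out: dict[str, pd.DataFrame] = {}
    for bait in design.baits:
        ap = condition_profile(
            matrix, design.bait_runs(bait), lengths, mode=profile_mode
        )
        quotients = compute_quotients(ap, wcl)
        out[bait] = compute_ref(quotients, reference, bait)
    return out


def nominate_candidates(
    records: Mapping[str, pd.DataFrame],
    *,
    member_threshold: float = DEFAULT_MEMBER_THRESHOLD,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> pd.DataFrame:
    """Rank non-reference preys as core-complex membership candidates.

    ``records`` maps bait_id -> REF table (from :func:`compute_ref`).
    A prey is *member-like* when its REF reaches ``member_threshold`` in
    every bait; the report lists every non-reference prey reaching
    ``report_threshold`` in at least one bait, ranked by minimum REF
    across baits (missing baits count as 0).
    """
    baits = list(records)
    if not baits:
        raise ValidationError("no REF records supplied")
    preys: set[str] = set()
    for table in records.values():
        preys |= set(table.index[~table["in_reference_set"]])
    rows = []
    for prey in sorted(preys):
        refs = {
            bait: float(records[bait]["ref"].get(prey, np.nan)) for bait in baits
        }
        vals = np.array([refs[b] for b in baits], dtype=float)
        filled = np.nan_to_num(vals, nan=0.0)
        rows.append(
            {
                "prey_id": prey,
                **{f"ref_{b}": refs[b] for b in baits},
                "min_ref": float(filled.min()),
                "max_ref": float(filled.max()),
                "member_like": bool((filled >= member_threshold).all()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["prey_id", *[f"ref_{b}" for b in baits], "min_ref", "max_ref", "member_like"],
    )
    table = table[table["max_ref"] >= report_threshold]
    table = table.sort_values(
        ["min_ref", "prey_id"], ascending=[False, True], kind="mergesort"
    )
    return table.reset_index(drop=True)
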