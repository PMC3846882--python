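"""Synthetic AP-MS experiment generator with a planted, recoverable truth.

The generator emulates the statistical structure of a streptavidin pull-down
study of a stable protein complex: a 12-member core complex, three of whose
members serve as overexpressed baits (three biological replicates each), a
mock-tag control run, a deep whole-cell-lysate (WCL) run, an abundant pool
of sticky contaminants present in both bait and control purifications, and
Poisson spectral-count noise on top of log-normal replicate-to-replicate
abundance jitter. Two engineered isoform pairs — an N-terminally extended
variant and an internal-deletion (junction) variant — plus one "candidate"
complex member excluded from the reference set exercise the peptide-level
and enrichment-level analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from apmsref.digest import DigestParams, nterm_processed_forms, tryptic_digest
from apmsref.io import (
    CONDITION_BAIT,
    CONDITION_CONTROL,
    CONDITION_WCL,
    ExperimentDesign,
    PeptideEvidence,
    ProteinRecord,
    SpectralCountMatrix,
    ValidationError,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NO_KRP = np.array([a for a in AA if a not in "KRP"])

LABEL_BAIT = "bait"
LABEL_CORE = "core"
LABEL_CANDIDATE = "candidate"
LABEL_BACKGROUND = "background"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic AP-MS experiment.

    ``bait_overexpression`` multiplies the bait's own abundance in its
    pull-downs (transient overexpression); ``complex_enrichment_range``
    bounds the per-member factor by which core members are enriched in
    bait purifications relative to their WCL abundance;
    ``sticky_binding`` is the fraction of WCL abundance at which sticky
    contaminants appear in any purification (bait or control).
    """

    seed: int = 0
    n_core: int = 12
    n_background: int = 200
    baits: tuple[int, ...] = (0, 1, 2)  # indices into the core members
    replicates: int = 3
    n_control: int = 1
    bait_overexpression: float = 4.0
    complex_enrichment_range: tuple[float, float] = (0.3, 1.7)
    candidate_enrichment: float = 0.5
    stickiness: float = 0.3
    sticky_binding: float = 0.1
    core_in_control: float = 0.0  # fraction of WCL abundance; 0 disables
    run_depth: float = 20_000.0
    wcl_depth: float = 100_000.0
    replicate_jitter_sigma: float = 0.2
    abundance_sigma: float = 1.0
    min_protein_length: int = 150
    max_protein_length: int = 1500

    def __post_init__(self) -> None:
        if self.n_core < 2 or self.n_background < 0:
            raise ValidationError("need n_core >= 2 and n_background >= 0")
        if not all(0 <= b < self.n_core for b in self.baits):
            raise ValidationError("baits must index core members")
        if min(self.bait_overexpression, self.candidate_enrichment) <= 0:
            raise ValidationError("abundance factors must be positive")
        if not (0 <= self.stickiness <= 1):
            raise ValidationError("stickiness must lie in [0, 1]")
        if min(self.run_depth, self.wcl_depth) <= 0:
            raise ValidationError("depths must be positive")


@dataclass
class GroundTruth:
    """Planted truth against which recovery is measured."""

    wcl_abundance: pd.Series  # unnormalised abundance weights, > 0
    pull_abundance: pd.DataFrame  # bait x protein weights (0 = absent)
    control_abundance: pd.Series
    labels: pd.Series  # bait | core | candidate | background
    complex_enrichment: pd.Series  # per core/candidate member
    bait_ids: list[str]
    candidate_id: str
    sticky_ids: list[str]
    isoform_groups: dict[str, list[str]]  # canonical -> variants
    junction_peptide: str

    @property
    def reference_ids(self) -> list[str]:
        """Core-complex members (baits included, candidate excluded)."""
        return list(self.labels.index[self.labels.isin([LABEL_BAIT, LABEL_CORE])])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _random_tract(rng: np.random.Generator, length: int) -> str:
    """Random residues containing no K/R/P (no internal cleavage sites)."""
    return "".join(rng.choice(_NO_KRP, size=length))


def _make_nextended_pair(rng: np.random.Generator) -> tuple[str, str]:
    """Canonical sequence plus a 24-residue N-terminal extension variant.

    The canonical starts with Met followed by an excision-permissive
    residue; the extension starts with Met and ends with K so that the
    canonical's Met-retained N-terminal peptide recurs as an internal
    tryptic peptide of the variant.
    """
    body = _random_sequence(rng, int(rng.integers(150, 400)))
    canonical = "M" + "A" + _random_tract(rng, 6) + "K" + body
    extension = "M" + _random_tract(rng, 12) + "R" + _random_tract(rng, 9) + "K"
    assert len(extension) == 24
    return canonical, extension + canonical


def _make_junction_pair(
    rng: np.random.Generator, max_tries: int = 50
) -> tuple[str, str, str]:
    """Canonical sequence and an internal-deletion variant.

    Deleting the block creates one tryptic junction peptide found in the
    variant only; its uniqueness across the final database is re-checked
    (and the pair regenerated if needed) by the caller.
    """
    head = _random_sequence(rng, int(rng.integers(60, 150)))
    head = head.rstrip("KR") + "K"
    for _ in range(max_tries):
        left = _random_tract(rng, 11)
        block = _random_tract(rng, 28) + "R"
        right = _random_tract(rng, 6) + "K"
        tail = _random_tract(rng, 1) + _random_sequence(rng, int(rng.integers(60, 200)))
        canonical = head + left + block + right + tail
        variant = head + left + right + tail
        junction = left + right  # 18 residues, flanked by cleavage sites
        if canonical.count(junction) == 0 and variant.count(junction) == 1:
            return canonical, variant, junction
    raise ValidationError("failed to engineer a unique junction peptide")


def generate_protein_db(
    config: SimConfig,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the protein database and its planted ground truth.

    Returns core members (the first ``len(config.baits)`` of which are the
    baits), one candidate complex member excluded from the reference set,
    the background contaminant pool, and two isoform pairs. Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}

    core_ids = [f"CORE{i + 1:02d}" for i in range(config.n_core)]
    bait_ids = [core_ids[i] for i in config.baits]
    for pid in core_ids:
        length = int(rng.integers(config.min_protein_length, config.max_protein_length + 1))
        records.append(ProteinRecord(pid, pid, _random_sequence(rng, length)))
        labels[pid] = LABEL_BAIT if pid in bait_ids else LABEL_CORE

    candidate_id = "CAND01"
    length = int(rng.integers(config.min_protein_length, config.max_protein_length + 1))
    records.append(ProteinRecord(candidate_id, candidate_id, _random_sequence(rng, length)))
    labels[candidate_id] = LABEL_CANDIDATE

    bg_ids = [f"BG{i + 1:03d}" for i in range(config.n_background)]
    for pid in bg_ids:
        length = int(rng.integers(config.min_protein_length, config.max_protein_length + 1))
        records.append(ProteinRecord(pid, pid, _random_sequence(rng, length)))
        labels[pid] = LABEL_BACKGROUND

    # isoform pair (a): N-terminally extended variant
    canon_a, ext_a = _make_nextended_pair(rng)
    # isoform pair (b): internal deletion with a unique junction peptide
    for _ in range(50):
        canon_b, var_b, junction = _make_junction_pair(rng)
        haystack = [r.sequence for r in records] + [canon_a, ext_a, canon_b]
        if sum(seq.count(junction) for seq in haystack) == 0:
            break
    else:  # pragma: no cover - astronomically unlikely at these lengths
        raise ValidationError("failed to place a database-unique junction peptide")
    iso_records = [
        ProteinRecord("ISOA1", "ISOA1", canon_a),
        ProteinRecord("ISOA2", "ISOA2", ext_a),
        ProteinRecord("ISOB1", "ISOB1", canon_b),
        ProteinRecord("ISOB2", "ISOB2", var_b),
    ]
    records.extend(iso_records)
    for rec in iso_records:
        labels[rec.protein_id] = LABEL_BACKGROUND
    isoform_groups = {"ISOA1": ["ISOA2"], "ISOB1": ["ISOB2"]}

    all_ids = [r.protein_id for r in records]
    labels_s = pd.Series(labels).loc[all_ids]

    # planted abundances
    wcl = pd.Series(
        rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(all_ids)),
        index=all_ids,
    )
    lo, hi = config.complex_enrichment_range
    enrichment = pd.Series(
        rng.uniform(lo, hi, size=config.n_core), index=core_ids
    )
    enrichment[candidate_id] = config.candidate_enrichment

    n_sticky = int(round(config.stickiness * config.n_background))
    sticky_ids = list(rng.choice(bg_ids, size=n_sticky, replace=False)) if n_sticky else []
    sticky_ids += [r.protein_id for r in iso_records]  # variants co-purify

    pull = pd.DataFrame(0.0, index=bait_ids, columns=all_ids)
    for bait in bait_ids:
        for pid in core_ids + [candidate_id]:
            pull.loc[bait, pid] = enrichment[pid] * wcl[pid]
        pull.loc[bait, bait] = config.bait_overexpression * wcl[bait]
        for pid in sticky_ids:
            pull.loc[bait, pid] = config.sticky_binding * wcl[pid]

    control = pd.Series(0.0, index=all_ids)
    control[sticky_ids] = config.sticky_binding * wcl[sticky_ids]
    if config.core_in_control > 0:
        for pid in core_ids + [candidate_id]:
            control[pid] = config.core_in_control * wcl[pid]

    truth = GroundTruth(
        wcl_abundance=wcl,
        pull_abundance=pull,
        control_abundance=control,
        labels=labels_s,
        complex_enrichment=enrichment,
        bait_ids=bait_ids,
        candidate_id=candidate_id,
        sticky_ids=sticky_ids,
        isoform_groups=isoform_groups,
        junction_peptide=junction,
    )
    return records, truth


def _draw_run(
    rng: np.random.Generator,
    weights: pd.Series,
    depth: float,
    jitter_sigma: float,
) -> np.ndarray:
    w = weights.to_numpy(dtype=float).copy()
    if jitter_sigma > 0:
        w *= rng.lognormal(mean=0.0, sigma=jitter_sigma, size=w.size)
    total = w.sum()
    if total <= 0:
        return np.zeros(w.size, dtype=np.int64)
    return rng.poisson(depth * w / total)


def simulate_apms_counts(
    db: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[SpectralCountMatrix, ExperimentDesign]:
    """Realise spectral counts for every run of the design.

    Per run, the expected count of protein *i* is ``depth`` times its
    relative abundance in that condition (after per-run log-normal jitter,
    renormalised so the expected run total equals the depth), drawn as an
    independent Poisson variate. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of db stream
    ids = [r.protein_id for r in db]
    rows: dict[str, np.ndarray] = {}
    design_rows = []

    for bait in truth.bait_ids:
        weights = truth.pull_abundance.loc[bait, ids]
        for rep in range(1, config.replicates + 1):
            run_id = f"AP_{bait}_r{rep}"
            rows[run_id] = _draw_run(
                rng, weights, config.run_depth, config.replicate_jitter_sigma
            )
            design_rows.append((run_id, CONDITION_BAIT, bait, rep))

    for rep in range(1, config.n_control + 1):
        run_id = f"CTRL_r{rep}"
        rows[run_id] = _draw_run(
            rng,
            truth.control_abundance.loc[ids],
            config.run_depth,
            config.replicate_jitter_sigma,
        )
        design_rows.append((run_id, CONDITION_CONTROL, "", rep))

    rows["WCL_r1"] = _draw_run(
        rng,
        truth.wcl_abundance.loc[ids],
        config.wcl_depth,
        config.replicate_jitter_sigma,
    )
    design_rows.append(("WCL_r1", CONDITION_WCL, "", 1))

    design = ExperimentDesign(
        pd.DataFrame(design_rows, columns=["run_id", "condition", "bait_id", "replicate"])
    )
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    matrix = SpectralCountMatrix(counts, design=design)
    return matrix, design


def generate_peptide_evidence(
    db: Sequence[ProteinRecord],
    truth: GroundTruth,
    matrix: SpectralCountMatrix,
    config: SimConfig,
    params: DigestParams | None = None,
) -> list[PeptideEvidence]:
    """Distribute isoform-group protein counts over their tryptic peptides.

    Each isoform protein's per-run spectral count is split multinomially
    (uniformly) across its fully-cleaved tryptic peptides, with the
    N-terminal peptide replaced by its processed forms (Met excision /
    +42 acetylation). Peptides are assigned to every database protein that
    contains them as a plain substring. Deterministic under ``config.seed``.
    """
    params = params or DigestParams()
    rng = np.random.default_rng(config.seed + 2)
    iso_ids = [p for pair in truth.isoform_groups.items() for p in (pair[0], *pair[1])]
    by_id = {rec.protein_id: rec for rec in db}
    zero_mc = DigestParams(
        max_missed_cleavages=0,
        min_length=params.min_length,
        cleave_after=params.cleave_after,
        suppress_before_proline=params.suppress_before_proline,
    )

    acc: dict[tuple[str, int], dict[str, int]] = {}
    for pid in iso_ids:
        rec = by_id[pid]
        digest = tryptic_digest(rec.sequence, zero_mc)
        forms: list[tuple[str, int]] = []
        for dp in digest:
            if dp.start == 1:
                forms.extend(
                    (f.sequence, f.nterm_mod_delta)
                    for f in nterm_processed_forms(rec, zero_mc)
                )
            else:
                forms.append((dp.sequence, 0))
        if not forms:
            continue
        probs = np.full(len(forms), 1.0 / len(forms))
        for run_id in matrix.run_ids:
            total = int(matrix.counts.loc[run_id, pid])
            if total == 0:
                continue
            split = rng.multinomial(total, probs)
            for (seq, delta), c in zip(forms, split):
                if c:
                    key = (seq, delta)
                    acc.setdefault(key, {})
                    acc[key][run_id] = acc[key].get(run_id, 0) + int(c)

    out = []
    for (seq, delta), counts in sorted(acc.items()):
        carriers = frozenset(
            rec.protein_id for rec in db if seq in rec.sequence
        ) or frozenset({"?"})
        out.append(
            PeptideEvidence(
                peptide_sequence=seq,
                nterm_mod_delta=delta,
                assigned_protein_ids=carriers,
                counts=counts,
            )
        )
    return out
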