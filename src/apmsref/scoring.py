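"""Probabilistic bait-prey interaction scoring from spectral counts.

Each bait-prey pair receives, per biological replicate, the posterior
probability that the prey's spectral count was drawn from an enriched
(true-interaction) Poisson component rather than the background component
estimated from mock-control purifications; the per-replicate probabilities
are averaged arithmetically and thresholded (default 0.9). This is a
deliberately simple, fully specified two-component model in the spirit of
spectral-count interaction scorers such as SAINT; it reproduces their
interface (per-replicate probability, replicate averaging, a 0.9 cut) with
desk-scale math rather than re-implementing any particular tool.

Model: for replicate r with observed count x_r and run depth d_r,

    p_r = f1(x_r) / (f0(x_r) + f1(x_r)),

where f0 is Poisson(d_r * lam0) with lam0 the prey's background rate per
unit depth (pseudocount-smoothed from control runs) and f1 is
Poisson(d_r * lam1) with lam1 the prey's mean rate over the bait's own
replicates, clamped from below by lam0 — equal prior odds. The clamp means
a prey depleted relative to control scores exactly 0.5 per replicate, never
above, so depletion alone cannot qualify an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from apmsref.io import ExperimentDesign, SpectralCountMatrix, ValidationError

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_PROBABILITY_THRESHOLD = 0.9
DEFAULT_MIN_SPECTRA = 2


@dataclass
class BackgroundModel:
    """Per-prey background rates (per unit depth) from control runs."""

    lam0: pd.Series  # strictly positive after pseudocount smoothing
    control_depth: float
    pseudocount: float

    def rate(self, prey_id: str) -> float:
        if prey_id in self.lam0.index:
            return float(self.lam0[prey_id])
        # prey never seen in controls and absent from the fitted index:
        # fall back to the pseudocount floor.
        return float(self.pseudocount / (self.control_depth + self.pseudocount * len(self.lam0)))


@dataclass(frozen=True)
class InteractionScore:
    """Scored bait-prey pair."""

    bait_id: str
    prey_id: str
    replicate_probabilities: tuple[float, ...]
    total_spectra: int
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD

    @property
    def average_probability(self) -> float:
        return float(np.mean(self.replicate_probabilities))

    @property
    def passes_threshold(self) -> bool:
        return self.average_probability >= self.threshold


def estimate_background(
    matrix: SpectralCountMatrix,
    design: ExperimentDesign,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BackgroundModel:
    """Fit per-prey background rates from the mock-control runs.

    lam0_i = (sum of prey i counts over controls + alpha) /
             (sum of control depths + alpha * n_proteins),

    with alpha the pseudocount, so every rate is strictly positive and a
    prey absent from all controls gets the floor value. Replicated controls
    are pooled depth-weighted: two identical control runs give the same
    rate as either alone.
    """
    controls = [r for r in design.control_runs if r in matrix.counts.index]
    if not controls:
        raise ValidationError(
            "no control runs in the experiment design; interaction scoring "
            "requires at least one mock-control purification"
        )
    block = matrix.counts.loc[controls]
    depth = float(block.to_numpy().sum())
    n = matrix.counts.shape[1]
    lam0 = (block.sum(axis=0) + pseudocount) / (depth + pseudocount * n)
    return BackgroundModel(lam0=lam0, control_depth=depth, pseudocount=pseudocount)


def posterior_probability(
    counts, depths, lam0: float, lam1: float
) -> np.ndarray:
    """P(enriched | count) under the two-component Poisson model.

    Equal prior odds: p = f1(x) / (f0(x) + f1(x)) with f_k the Poisson pmf
    at mean depth * lam_k, evaluated in log space for stability.
    """
    x = np.asarray(counts, dtype=float)
    d = np.asarray(depths, dtype=float)
    log_f0 = poisson.logpmf(x, d * lam0)
    log_f1 = poisson.logpmf(x, d * lam1)
    return 1.0 / (1.0 + np.exp(np.clip(log_f0 - log_f1, -700, 700)))


def score_pair(
    bait_counts: Sequence[int],
    depths: Sequence[float],
    lam0: float,
) -> tuple[float, ...]:
    """Per-replicate posterior probabilities for one bait-prey pair.

    ``bait_counts`` and ``depths`` are the prey's spectral counts and the
    total spectra of the bait's replicate runs. lam1 is the prey's pooled
    rate over those replicates (method of moments), clamped to at least
    ``lam0`` so depletion relative to control never scores above 0.5.
    """
    x = np.asarray(bait_counts, dtype=float)
    d = np.asarray(depths, dtype=float)
    if x.shape != d.shape or x.size == 0:
        raise ValidationError("bait_counts and depths must align and be non-empty")
    if (d <= 0).any():
        raise ValidationError("zero-depth run encountered while scoring")
    if lam0 <= 0:
        raise ValidationError("background rate must be strictly positive")
    lam1 = max(float(x.sum() / d.sum()), lam0)
    p = posterior_probability(x, d, lam0, lam1)
    return tuple(float(v) for v in p)


def score_all(
    matrix: SpectralCountMatrix,
    design: ExperimentDesign,
    model: BackgroundModel | None = None,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Score every bait-prey pair in the matrix.

    Returns a tidy frame with one row per (bait, prey): per-replicate
    probabilities, their arithmetic mean, total spectra in the bait's
    replicates, and the threshold flag. The bait's own accession is scored
    like any other prey (it is trivially enriched).
    """
    if model is None:
        model = estimate_background(matrix, design, pseudocount)
    depths = matrix.run_depths()
    rows = []
    n_rep_max = 0
    for bait in design.baits:
        runs = [r for r in design.bait_runs(bait) if r in matrix.counts.index]
        if not runs:
            continue
        d = depths.loc[runs].to_numpy()
        n_rep_max = max(n_rep_max, len(runs))
        block = matrix.counts.loc[runs]
        for prey in matrix.protein_ids:
            x = block[prey].to_numpy()
            total = int(x.sum())
            if total == 0:
                continue
            probs = score_pair(x, d, model.rate(prey))
            avg = float(np.mean(probs))
            rows.append(
                {
                    "bait_id": bait,
                    "prey_id": prey,
                    **{f"p_rep{i + 1}": p for i, p in enumerate(probs)},
                    "avg_prob": avg,
                    "total_spectra": total,
                    "passes_threshold": avg >= threshold,
                }
            )
    prob_cols = [f"p_rep{i + 1}" for i in range(n_rep_max)]
    cols = ["bait_id", "prey_id", *prob_cols, "avg_prob", "total_spectra", "passes_threshold"]
    return pd.DataFrame(rows, columns=cols)


def filter_interactome(
    scores: pd.DataFrame,
    *,
    min_spectra: int = DEFAULT_MIN_SPECTRA,
) -> pd.DataFrame:
    """Qualified prey list per bait.

    Qualified = passes the probability threshold and carries at least
    ``min_spectra`` total spectra in the bait's replicate series. Sorted by
    average probability (descending), ties broken by total spectral count
    (descending) then accession (ascending).
    """
    if scores.empty:
        return scores.copy()
    qualified = scores[
        scores["passes_threshold"] & (scores["total_spectra"] >= min_spectra)
    ].copy()
    qualified = qualified.sort_values(
        ["bait_id", "avg_prob", "total_spectra", "prey_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return qualified.reset_index(drop=True)
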