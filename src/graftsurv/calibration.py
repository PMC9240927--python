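"""Risk-bin baseline-hazard calibration of time-varying risk scores.

A ranking-trained hazard network orders individuals well but its raw
outputs need not be calibrated probabilities.  This module treats the
raw per-interval hazards as time-varying relative risk scores R[i, t]
and rescales them with per-time-step, per-risk-bin baseline hazards:

    calibrated_hazard[i, t] = R[i, t] * BH[k(i,t), t],

where bin k(i, t) is found from per-time-step n-quantile cutoffs of the
training scores, and the bin baseline hazard is the Breslow-style ratio

    BH[k, t] = d_k(t) / sum_{i in R_k(t)} R[i, t]

with d_k(t) the number of observed events in interval t among bin-k
members and R_k(t) the bin-k individuals still at risk at t.  By
construction the calibrated hazards of each bin's risk set sum exactly
to that bin's event count on the training data.  With a single bin and
unit scores this collapses to the pooled empirical discrete hazard.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import HazardMatrix, SurvivalDataset, TimeGrid

__all__ = [
    "RiskBinModel",
    "fit_risk_bins",
    "assign_bins",
    "estimate_bin_baseline_hazards",
    "estimate_global_baseline_hazard",
    "calibrate_hazards",
]


def fit_risk_bins(training_scores: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-time-step quantile cutoffs of the training risk scores.

    Returns an ``(n_bins - 1, N)`` matrix whose column t holds the
    (1/n, ..., (n-1)/n) quantiles (linear interpolation between order
    statistics) of the scores at time step t.
    """
    scores = np.asarray(training_scores, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scores.shape[0] < n_bins:
        raise ValueError("need at least n_bins training rows")
    if n_bins == 1:
        return np.empty((0, scores.shape[1]))
    qs = np.arange(1, n_bins) / n_bins
    return np.quantile(scores, qs, axis=0)


def assign_bins(scores: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """0-based bin index per (individual, time step); ties go to the upper bin.

    ``k[i, t]`` counts the cutoffs at step t that are <= R[i, t], so scores
    outside the training range simply land in the outer bins.
    """
    scores = np.asarray(scores, dtype=float)
    if cutoffs.size == 0:
        return np.zeros(scores.shape, dtype=int)
    return (cutoffs[None, :, :] <= scores[:, None, :]).sum(axis=1)


@dataclass
class RiskBinModel:
    """Per-time-step risk-bin cutoffs and bin baseline hazards."""

    n_bins: int
    cutoffs: np.ndarray            # (n_bins - 1, N)
    baseline_hazards: np.ndarray   # (n_bins, N)
    event_counts: np.ndarray       # (n_bins, N), diagnostics
    grid: TimeGrid

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutoffs, axis=0) < -1e-12):
            raise ValueError("cutoffs must be non-decreasing within each time step")
        if np.any(self.baseline_hazards < 0):
            raise ValueError("baseline hazards must be non-negative")

    # -- fitting ---------------------------------------------------------
    @classmethod
    def fit(
        cls,
        training_data: SurvivalDataset,
        training_scores: np.ndarray,
        grid: TimeGrid | None = None,
        n_bins: int = 10,
    ) -> "RiskBinModel":
        grid = grid or TimeGrid()
        cutoffs = fit_risk_bins(training_scores, n_bins)
        return estimate_bin_baseline_hazards(
            training_data, training_scores, cutoffs, grid, n_bins
        )

    def assign(self, scores: np.ndarray) -> np.ndarray:
        return assign_bins(scores, self.cutoffs)

    def calibrate(self, scores: np.ndarray) -> HazardMatrix:
        return calibrate_hazards(scores, self)

    # -- serialisation ---------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "n_bins": int(self.n_bins),
            "cutoffs": self.cutoffs.tolist(),
            "baseline_hazards": self.baseline_hazards.tolist(),
            "event_counts": self.event_counts.tolist(),
            "grid": {
                "horizon_years": self.grid.horizon_years,
                "step_years": self.grid.step_years,
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "RiskBinModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            n_bins=doc["n_bins"],
            cutoffs=np.asarray(doc["cutoffs"], dtype=float).reshape(doc["n_bins"] - 1, -1),
            baseline_hazards=np.asarray(doc["baseline_hazards"], dtype=float),
            event_counts=np.asarray(doc["event_counts"], dtype=float),
            grid=TimeGrid(**doc["grid"]),
        )


def estimate_bin_baseline_hazards(
    training_data: SurvivalDataset,
    training_scores: np.ndarray,
    cutoffs: np.ndarray,
    grid: TimeGrid | None = None,
    n_bins: int | None = None,
) -> RiskBinModel:
    """Breslow-style bin baseline hazards from a discretised training cohort.

    ``BH[k, t] = d_k(t) / sum of R[i, t] over bin-k individuals at risk at t``,
    set to 0 when the denominator (equivalently the bin's risk set) is empty.
    """
    grid = grid or TimeGrid()
    scores = np.asarray(training_scores, dtype=float)
    if n_bins is None:
        n_bins = cutoffs.shape[0] + 1
    n, N = scores.shape
    if N != grid.n_intervals:
        raise ValueError("score columns must match the grid")
    intervals, events = training_data.discretize(grid)

    bins = assign_bins(scores, cutoffs)                  # (n, N)
    steps = np.arange(1, N + 1)
    at_risk = intervals[:, None] >= steps[None, :]       # (n, N)
    event_here = events[:, None] & (intervals[:, None] == steps[None, :])

    d = np.zeros((n_bins, N))
    denom = np.zeros((n_bins, N))
    for k in range(n_bins):
        in_bin = bins == k
        d[k] = (in_bin & event_here).sum(axis=0)
        denom[k] = np.where(in_bin & at_risk, scores, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bh = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    return RiskBinModel(
        n_bins=n_bins,
        cutoffs=np.asarray(cutoffs, dtype=float),
        baseline_hazards=bh,
        event_counts=d,
        grid=grid,
    )


def estimate_global_baseline_hazard(
    training_data: SurvivalDataset,
    training_scores: np.ndarray,
    grid: TimeGrid | None = None,
) -> np.ndarray:
    """Single-bin special case: BH(t) = d(t) / sum of at-risk scores at t."""
    grid = grid or TimeGrid()
    model = estimate_bin_baseline_hazards(
        training_data, training_scores, np.empty((0, np.asarray(training_scores).shape[1])),
        grid, n_bins=1,
    )
    return model.baseline_hazards[0]


def calibrate_hazards(scores: np.ndarray, bin_model: RiskBinModel) -> HazardMatrix:
    """Calibrated hazards ``R[i,t] * BH[k(i,t), t]``, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != bin_model.baseline_hazards.shape[1]:
        raise ValueError("score columns do not match the bin model")
    bins = bin_model.assign(scores)
    bh = bin_model.baseline_hazards[bins, np.arange(scores.shape[1])[None, :]]
    h = scores * bh
    n_clipped = int((h > 1.0).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} calibrated hazards exceeded 1 and were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return HazardMatrix(np.clip(h, 0.0, 1.0), bin_model.grid)
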