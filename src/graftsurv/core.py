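"""Core containers for discrete-time survival analysis.

Graft survival is modelled on a discrete grid of ``n_intervals`` equal steps
(by default 60 quarterly steps spanning 15 years after transplantation).
Interval ``t`` (1-based) covers the half-open span ``((t-1)*step, t*step]``:
an observation falling exactly on a boundary belongs to the earlier interval.

The conditional (discrete) hazard ``h[i, t]`` is the probability that
individual ``i`` fails in interval ``t`` given survival to its start; the
survival probability at the end of interval ``t`` is the product
``S[i, t] = prod_{s<=t} (1 - h[i, s])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "SurvivalDataset",
    "HazardMatrix",
    "SurvivalMatrix",
    "discretize_event",
    "discretize_events",
    "hazards_to_survival",
    "survival_to_failure",
]

#: reserved column names of the cohort CSV dialect
TIME_COLUMN = "time_years"
EVENT_COLUMN = "event"
GROUP_COLUMN = "group"


@dataclass(frozen=True)
class TimeGrid:
    """Uniform discrete prediction grid.

    Parameters
    ----------
    horizon_years : float
        Total follow-up horizon (default 15 years).
    step_years : float
        Width of one interval (default 0.25 years, i.e. quarterly).
    """

    horizon_years: float = 15.0
    step_years: float = 0.25

    def __post_init__(self) -> None:
        if self.horizon_years <= 0 or self.step_years <= 0:
            raise ValueError("horizon_years and step_years must be positive")
        ratio = self.horizon_years / self.step_years
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "horizon_years must be an exact positive multiple of step_years"
            )

    @property
    def n_intervals(self) -> int:
        return int(round(self.horizon_years / self.step_years))

    @property
    def interval_ends(self) -> np.ndarray:
        """End times ``t*step`` of the N intervals, in years."""
        return self.step_years * np.arange(1, self.n_intervals + 1)

    def interval_of(self, time_years: float) -> int:
        """1-based interval containing ``time_years`` (capped at N)."""
        idx, _ = discretize_event(time_years, True, self)
        return idx


def discretize_event(
    observed_time: float, event_observed: bool, grid: TimeGrid
) -> tuple[int, bool]:
    """Map a continuous observation onto the discrete grid.

    Returns the 1-based interval index (smallest ``t`` with
    ``observed_time <= t*step``) and whether the event falls inside the
    horizon.  Observations beyond the horizon are administratively censored
    at interval N.
    """
    if observed_time <= 0:
        raise ValueError(f"observed_time must be positive, got {observed_time}")
    n = grid.n_intervals
    # round guards against float noise at exact interval boundaries
    idx = int(np.ceil(round(observed_time / grid.step_years, 9)))
    if idx > n:
        return n, False
    return max(idx, 1), bool(event_observed)


def discretize_events(
    observed_time: np.ndarray, event_observed: np.ndarray, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`discretize_event` over a cohort."""
    observed_time = np.asarray(observed_time, dtype=float)
    event_observed = np.asarray(event_observed, dtype=bool)
    if np.any(observed_time <= 0):
        raise ValueError("observed_time must be positive for all individuals")
    idx = np.ceil(np.round(observed_time / grid.step_years, 9)).astype(int)
    idx = np.maximum(idx, 1)
    beyond = idx > grid.n_intervals
    idx = np.where(beyond, grid.n_intervals, idx)
    events = event_observed & ~beyond
    return idx, events


@dataclass
class SurvivalDataset:
    """A cohort: covariate matrix, observed times and event indicators.

    ``event_observed`` is stored with positive polarity (True = graft
    failure observed); censoring indicators needed by loss functions are
    derived as ``1 - event_observed`` where required.
    """

    covariates: np.ndarray
    observed_time: np.ndarray
    event_observed: np.ndarray
    column_names: list[str]
    group_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2:
            raise ValueError("covariates must be a 2-D matrix")
        self.observed_time = np.asarray(self.observed_time, dtype=float)
        self.event_observed = np.asarray(self.event_observed, dtype=bool)
        n = self.covariates.shape[0]
        if self.observed_time.shape != (n,) or self.event_observed.shape != (n,):
            raise ValueError("times/events must align with covariate rows")
        if len(self.column_names) != self.covariates.shape[1]:
            raise ValueError("column_names must match covariate columns")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing/non-finite values")
        if np.any(self.observed_time <= 0):
            raise ValueError("observed_time must be positive")
        if self.group_label is not None:
            self.group_label = np.asarray(self.group_label, dtype=object)
            if self.group_label.shape != (n,):
                raise ValueError("group_label must align with covariate rows")

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_features(self) -> int:
        return self.covariates.shape[1]

    def discretize(self, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
        """1-based event intervals and in-horizon event flags."""
        return discretize_events(self.observed_time, self.event_observed, grid)

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            covariates=self.covariates[index],
            observed_time=self.observed_time[index],
            event_observed=self.event_observed[index],
            column_names=list(self.column_names),
            group_label=None if self.group_label is None else self.group_label[index],
        )

    # ------------------------------------------------------------------
    # I/O: cohort CSV dialect (reserved columns time_years, event, group)
    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, categorical_columns: list[str] | None = None
    ) -> "SurvivalDataset":
        """Build a dataset from a tidy frame, one-hot expanding categoricals.

        Categorical levels are expanded in lexicographic order with columns
        named ``<variable>=<level>`` so that the expansion is deterministic.
        """
        if TIME_COLUMN not in df or EVENT_COLUMN not in df:
            raise ValueError(
                f"dataframe must contain '{TIME_COLUMN}' and '{EVENT_COLUMN}' columns"
            )
        categorical_columns = list(categorical_columns or [])
        group = df[GROUP_COLUMN].to_numpy() if GROUP_COLUMN in df else None
        cov = df.drop(
            columns=[c for c in (TIME_COLUMN, EVENT_COLUMN, GROUP_COLUMN) if c in df]
        )
        blocks: list[pd.DataFrame] = []
        for name in cov.columns:
            col = cov[name]
            if name in categorical_columns or col.dtype == object:
                levels = sorted(map(str, pd.unique(col.astype(str))))
                onehot = pd.DataFrame(
                    {f"{name}={lv}": (col.astype(str) == lv).astype(float) for lv in levels}
                )
                blocks.append(onehot)
            else:
                blocks.append(col.astype(float).to_frame())
        matrix = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
        return cls(
            covariates=matrix.to_numpy(dtype=float),
            observed_time=df[TIME_COLUMN].to_numpy(dtype=float),
            event_observed=df[EVENT_COLUMN].to_numpy(dtype=float).astype(bool),
            column_names=list(matrix.columns),
            group_label=group,
        )

    @classmethod
    def from_csv(
        cls, path, categorical_columns: list[str] | None = None
    ) -> "SurvivalDataset":
        return cls.from_dataframe(pd.read_csv(path), categorical_columns)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.column_names)
        df[TIME_COLUMN] = self.observed_time
        df[EVENT_COLUMN] = self.event_observed.astype(int)
        if self.group_label is not None:
            df[GROUP_COLUMN] = self.group_label
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_matrix(values: np.ndarray, grid: TimeGrid, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{name} values must be 2-D")
    if values.shape[1] != grid.n_intervals:
        raise ValueError(
            f"{name} has {values.shape[1]} columns, grid expects {grid.n_intervals}"
        )
    return values


@dataclass
class HazardMatrix:
    """Per-individual, per-interval conditional hazards (n x N) in [0, 1]."""

    values: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, self.grid, "HazardMatrix")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("hazards must lie in [0, 1]")


@dataclass
class SurvivalMatrix:
    """Per-individual survival probabilities S[i, t] at interval ends."""

    values: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, self.grid, "SurvivalMatrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")

    def at_time(self, t_years: float) -> np.ndarray:
        """Survival at the end of the interval containing ``t_years``."""
        return self.values[:, self.grid.interval_of(t_years) - 1]

    def failure(self) -> np.ndarray:
        return survival_to_failure(self)


def hazards_to_survival(h: HazardMatrix) -> SurvivalMatrix:
    """Discrete-time identity S[i,t] = prod_{s<=t} (1 - h[i,s])."""
    return SurvivalMatrix(np.cumprod(1.0 - h.values, axis=1), h.grid)


def survival_to_failure(S: SurvivalMatrix) -> np.ndarray:
    """Cumulative failure probability F = 1 - S, elementwise."""
    return 1.0 - S.values
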