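"""Evaluation suite for discrete-time survival predictions.

Discrimination is measured with the Harrell concordance index (one scalar
risk score per individual) and the Antolini time-dependent concordance
index (full survival curves, compared at the earlier event time), both
with the convention that tied scores count 0.5 and tied event times are
not comparable.  Accuracy is measured with the inverse-probability-of-
censoring-weighted (IPCW) Brier score and its average over the grid (the
integrated Brier score); the censoring distribution G(t) = P[censoring
time > t] is estimated by a Kaplan-Meier fit with flipped event
indicators, and event contributions are weighted by the left limit
G(t-).  Calibration at a horizon t* is assessed by decile grouping or by
regression of the observed failure rate on a restricted-cubic-spline
expansion of cloglog(predicted failure), summarised by the integrated
calibration index (ICI), the mean absolute gap between predicted and
estimated observed failure probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SurvivalDataset, SurvivalMatrix, TimeGrid, discretize_events

__all__ = [
    "KaplanMeierEstimate",
    "CensoringEstimate",
    "CalibrationCurve",
    "MetricReport",
    "kaplan_meier",
    "harrell_cindex",
    "antolini_cindex",
    "brier_score",
    "integrated_brier",
    "decile_calibration",
    "spline_calibration",
    "ici",
    "evaluate_model",
]


# ----------------------------------------------------------------------
# Kaplan-Meier product-limit estimator
# ----------------------------------------------------------------------
@dataclass
class KaplanMeierEstimate:
    """Right-continuous product-limit step function.

    ``__call__(t)`` evaluates S(t); ``left(t)`` evaluates the left limit
    S(t-), needed for IPCW weights at event times.
    """

    event_times: np.ndarray   # unique times with at least one event, sorted
    survival: np.ndarray      # S just after each event time

    def __call__(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.survival])[idx]
        return float(vals) if np.isscalar(t) else vals

    def left(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate([[1.0], self.survival])[idx]
        return float(vals) if np.isscalar(t) else vals


def kaplan_meier(times: np.ndarray, event_flags: np.ndarray) -> KaplanMeierEstimate:
    """Product-limit survival estimate S(t) = prod_{t_k <= t} (1 - d_k / n_k)."""
    times = np.asarray(times, dtype=float)
    event_flags = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("kaplan_meier requires at least one observation")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], event_flags[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    counts = np.diff(np.append(start, t_sorted.size))
    d = np.add.reduceat(e_sorted.astype(float), start)
    n_at_risk = times.size - np.append(0, np.cumsum(counts))[:-1]
    has_event = d > 0
    factors = 1.0 - d[has_event] / n_at_risk[has_event]
    return KaplanMeierEstimate(
        event_times=uniq[has_event], survival=np.cumprod(factors)
    )


@dataclass
class CensoringEstimate:
    """KM estimate of the censoring distribution G(t) = P[C > t]."""

    km: KaplanMeierEstimate

    @classmethod
    def fit(cls, times: np.ndarray, event_flags: np.ndarray) -> "CensoringEstimate":
        # flipped indicators: censorings are the "events", events are censored
        return cls(kaplan_meier(times, ~np.asarray(event_flags, dtype=bool)))

    def __call__(self, t):
        return self.km(t)

    def left(self, t):
        return self.km.left(t)


# ----------------------------------------------------------------------
# Concordance indexes
# ----------------------------------------------------------------------
def _concordance(conc: float, comp: float) -> float:
    if comp == 0:
        raise ValueError("no comparable pairs: concordance is undefined")
    return conc / comp


def harrell_cindex(
    risk_scores: np.ndarray, times: np.ndarray, event_flags: np.ndarray,
    chunk: int = 512,
) -> float:
    """Harrell concordance: pair (i, j) is comparable iff t_i < t_j and i had
    the event; concordant iff score_i > score_j; score ties count 0.5."""
    s = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if not (s.shape == t.shape == e.shape) or s.ndim != 1:
        raise ValueError("risk_scores, times and event_flags must be aligned vectors")
    ev = np.flatnonzero(e)
    conc = comp = 0.0
    for start in range(0, ev.size, chunk):
        i = ev[start : start + chunk]
        comparable = t[i][:, None] < t[None, :]
        comp += comparable.sum()
        diff = s[i][:, None] - s[None, :]
        conc += np.where(comparable, (diff > 0) + 0.5 * (diff == 0), 0.0).sum()
    return _concordance(conc, comp)


def antolini_cindex(
    S: SurvivalMatrix | np.ndarray,
    intervals: np.ndarray,
    event_flags: np.ndarray,
    chunk: int = 512,
) -> float:
    """Time-dependent concordance of Antolini: pair (i, j) with an event for
    i at interval t_i earlier than j's observed interval is concordant iff
    S_i(t_i) < S_j(t_i); ties count 0.5."""
    Sv = S.values if isinstance(S, SurvivalMatrix) else np.asarray(S, dtype=float)
    k = np.asarray(intervals, dtype=int)
    e = np.asarray(event_flags, dtype=bool)
    ev = np.flatnonzero(e)
    conc = comp = 0.0
    for start in range(0, ev.size, chunk):
        i = ev[start : start + chunk]
        cols = k[i] - 1
        comparable = k[i][:, None] < k[None, :]
        comp += comparable.sum()
        Si = Sv[i, cols][:, None]            # S_i(t_i)
        Sj = Sv[:, cols].T                   # S_j(t_i), shape (chunk, n)
        diff = Sj - Si
        conc += np.where(comparable, (diff > 0) + 0.5 * (diff == 0), 0.0).sum()
    return _concordance(conc, comp)


# ----------------------------------------------------------------------
# IPCW Brier score
# ----------------------------------------------------------------------
def _brier_at(
    S_col: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    t_star: float,
    G: CensoringEstimate,
) -> tuple[float, int]:
    event_before = events & (times <= t_star)
    at_risk_after = times > t_star
    w_event = np.where(event_before, G.left(times), 1.0)
    w_after = G(t_star)
    usable = np.ones(times.size, dtype=bool)
    usable[event_before & (w_event <= 0)] = False
    if np.any(at_risk_after) and w_after <= 0:
        usable[at_risk_after] = False
    contrib = np.zeros(times.size)
    m = event_before & usable
    contrib[m] = S_col[m] ** 2 / w_event[m]
    m = at_risk_after & usable
    if np.any(m):
        contrib[m] = (1.0 - S_col[m]) ** 2 / w_after
    n_used = int(usable.sum())
    n_dropped = times.size - n_used
    if n_used == 0:
        raise ValueError(f"no usable observations for Brier score at t*={t_star}")
    return float(contrib[usable].sum() / n_used), n_dropped


def brier_score(
    S: SurvivalMatrix,
    times: np.ndarray,
    event_flags: np.ndarray,
    t_star: float,
) -> float:
    """IPCW Brier score at horizon ``t_star`` (on the prediction grid).

    Individuals with an event by t* contribute S_i(t*)^2 / G(t_i-), those
    still at risk past t* contribute (1 - S_i(t*))^2 / G(t*), and those
    censored before t* contribute 0.  Individuals whose IPCW weight would
    be 1/0 are excluded with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    G = CensoringEstimate.fit(times, events)
    value, n_dropped = _brier_at(S.at_time(t_star), times, events, t_star, G)
    if n_dropped:
        warnings.warn(
            f"Brier score at t*={t_star}: dropped {n_dropped} observations with "
            "zero censoring-survival weight",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def integrated_brier(
    S: SurvivalMatrix,
    times: np.ndarray,
    event_flags: np.ndarray,
    grid: TimeGrid | None = None,
) -> float:
    """Arithmetic mean of the IPCW Brier score over all grid intervals."""
    grid = grid or S.grid
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    G = CensoringEstimate.fit(times, events)
    values = [
        _brier_at(S.values[:, t], times, events, t_star, G)[0]
        for t, t_star in enumerate(grid.interval_ends)
    ]
    return float(np.mean(values))


# ----------------------------------------------------------------------
# Calibration
# ----------------------------------------------------------------------
@dataclass
class CalibrationCurve:
    """Paired predicted / estimated-observed failure probabilities at t*."""

    t_star: float
    predicted: np.ndarray
    observed: np.ndarray
    method: str  # "decile" or "spline"

    def __post_init__(self) -> None:
        order = np.argsort(self.predicted, kind="stable")
        self.predicted = np.asarray(self.predicted, dtype=float)[order]
        self.observed = np.asarray(self.observed, dtype=float)[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"predicted": self.predicted, "observed": self.observed})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
        ax.plot(self.predicted, self.observed, marker="o" if self.method == "decile" else None)
        ax.set_xlabel(f"predicted failure probability by {self.t_star} y")
        ax.set_ylabel("observed failure probability")
        return ax


def ici(curve: CalibrationCurve) -> float:
    """Integrated calibration index: mean |predicted - estimated observed|."""
    return float(np.mean(np.abs(curve.predicted - curve.observed)))


def decile_calibration(
    F_pred: np.ndarray,
    times: np.ndarray,
    event_flags: np.ndarray,
    t_star: float,
    n_groups: int = 10,
) -> CalibrationCurve:
    """Group by predicted-probability quantiles; per group pair the mean
    prediction with 1 - KM(t*) of the group (duplicate cutoffs merge
    adjacent groups)."""
    F_pred = np.asarray(F_pred, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if F_pred.size < n_groups:
        raise ValueError("need at least n_groups individuals")
    try:
        labels = pd.qcut(F_pred, n_groups, labels=False, duplicates="drop")
    except ValueError:  # all predictions identical -> a single group
        labels = np.zeros(F_pred.size, dtype=int)
    if np.all(pd.isna(labels)):
        labels = np.zeros(F_pred.size, dtype=int)
    labels = np.asarray(labels, dtype=int)
    preds, obs = [], []
    for g in np.unique(labels):
        m = labels == g
        preds.append(F_pred[m].mean())
        obs.append(1.0 - kaplan_meier(times[m], events[m])(t_star))
    return CalibrationCurve(t_star, np.array(preds), np.array(obs), "decile")


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (truncated power form, linear tails)."""
    k = np.asarray(knots, dtype=float)
    m = k.size
    denom = (k[-1] - k[0]) ** 2
    cols = [x]
    for j in range(m - 2):
        term = (
            np.maximum(x - k[j], 0) ** 3
            - np.maximum(x - k[-2], 0) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
            + np.maximum(x - k[-1], 0) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


def spline_calibration(
    F_pred: np.ndarray,
    times: np.ndarray,
    event_flags: np.ndarray,
    t_star: float,
    n_knots: int = 4,
) -> CalibrationCurve:
    """Smooth calibration curve at t*.

    The observed failure rate is modelled as a function of
    cloglog(F_pred) = log(-log(1 - F_pred)) through a proportional-hazards
    regression on a restricted cubic spline basis (``n_knots`` knots at
    quantiles of the transformed predictions); the estimated observed
    failure probability is evaluated at every individual's prediction.
    Degenerate predictions fall back to the decile method with a warning.
    """
    from lifelines import CoxPHFitter

    F_pred = np.asarray(F_pred, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    F_clip = np.clip(F_pred, 1e-10, 1 - 1e-10)
    x = np.log(-np.log(1.0 - F_clip))
    if np.std(x) < 1e-10:
        warnings.warn(
            "spline calibration: predictions are degenerate, falling back to deciles",
            RuntimeWarning,
            stacklevel=2,
        )
        return decile_calibration(F_pred, times, events, t_star, n_groups=1)
    # Harrell's knot placement for 4 knots: 5th/35th/65th/95th percentiles
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(x, qs))
    if knots.size < 3:
        basis = x[:, None]
    else:
        basis = _rcs_basis(x, knots)
    df = pd.DataFrame(basis, columns=[f"s{j}" for j in range(basis.shape[1])])
    df["T"] = times
    df["E"] = events.astype(int)
    try:
        cph = CoxPHFitter(penalizer=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
            surv = cph.predict_survival_function(
                df.drop(columns=["T", "E"]), times=[t_star]
            )
    except Exception as err:  # singular fits on degenerate inputs
        warnings.warn(
            f"spline calibration fit failed ({err}); falling back to deciles",
            RuntimeWarning,
            stacklevel=2,
        )
        return decile_calibration(F_pred, times, events, t_star)
    F_obs = 1.0 - surv.to_numpy()[0]
    return CalibrationCurve(t_star, F_pred, F_obs, "spline")


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------
@dataclass
class MetricReport:
    """C-indexes, Brier/IBS and ICI values plus the settings that produced them."""

    harrell_c: float
    antolini_c: float
    ibs: float
    brier: dict[str, float]
    ici: dict[str, float]
    settings: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "harrell_c": self.harrell_c,
                "antolini_c": self.antolini_c,
                "ibs": self.ibs,
                "brier": self.brier,
                "ici": self.ici,
                "settings": self.settings,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MetricReport":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        return cls(**doc)


def evaluate_model(
    S: SurvivalMatrix,
    data: SurvivalDataset,
    grid: TimeGrid | None = None,
    horizons: tuple[float, ...] = (1.0, 5.0, 15.0),
    calibration_method: str = "spline",
    settings: dict | None = None,
) -> MetricReport:
    """Full metric battery for a matrix of predicted survival curves.

    The Harrell C-index uses the predicted cumulative failure probability
    at the final horizon as the scalar risk score.
    """
    grid = grid or S.grid
    times = data.observed_time
    events = data.event_observed
    intervals, events_h = discretize_events(times, events, grid)

    harrell = harrell_cindex(1.0 - S.values[:, -1], times, events)
    antolini = antolini_cindex(S, intervals, events_h)
    ibs = integrated_brier(S, times, events, grid)
    brier = {}
    ici_values = {}
    calibrate = spline_calibration if calibration_method == "spline" else decile_calibration
    for t_star in horizons:
        key = f"{t_star:g}y"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            brier[key] = brier_score(S, times, events, t_star)
        F_pred = 1.0 - S.at_time(t_star)
        ici_values[key] = ici(calibrate(F_pred, times, events, t_star))
    return MetricReport(
        harrell_c=harrell,
        antolini_c=antolini,
        ibs=ibs,
        brier=brier,
        ici=ici_values,
        settings=dict(settings or {}, calibration=calibration_method,
                      horizons=list(horizons)),
    )
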