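"""Training objectives for the discrete-time recurrent hazard model.

Two candidate losses are provided:

* ``ranking`` — the pairwise ranking loss of DeepHit.  For every
  acceptable ordered pair (i uncensored, with event interval t_i strictly
  before j's observed interval) the penalty is
  ``eta(F_i(t_i), F_j(t_i)) = exp(-(F_i(t_i) - F_j(t_i)) / sigma)``,
  where F is the cumulative failure probability.  The loss is the
  ``alpha``-weighted mean of the pair penalties, so a well-ranked pair
  (F_i much larger than F_j at t_i) contributes ~0 and a tied pair
  contributes 1 before weighting.  This objective rewards correct ordering
  only; it carries no pressure towards absolute calibration, which is the
  role of the downstream risk-bin calibration step.

* ``likelihood`` — the discrete-time survival likelihood used by deep
  recurrent survival analysis: for an uncensored individual, the negative
  log of the probability mass at the event interval,
  ``p_i(t) = h[i,t] * prod_{s<t}(1 - h[i,s])``; for a censored individual,
  the negative log of the survival probability at the censoring interval.

Censoring indicators follow the convention ``c_i = 0`` for an observed
event; public entry points accept either ``c`` or the package's positive
``event_observed`` polarity via ``c = 1 - event_observed``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ranking_loss", "likelihood_loss"]

_EPS = 1e-7  # probability clipping floor, avoids -log(0)


def _validate(n_rows: int, intervals: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    intervals = np.asarray(intervals, dtype=int)
    c = np.asarray(c, dtype=int)
    if intervals.shape != (n_rows,) or c.shape != (n_rows,):
        raise ValueError("event_intervals and censoring indicators must align with rows")
    return intervals, c


def ranking_loss(
    F: np.ndarray,
    event_intervals: np.ndarray,
    c: np.ndarray,
    alpha: float = 0.1,
    sigma: float = 0.1,
) -> float:
    """DeepHit-style pairwise ranking loss on a cumulative-failure matrix.

    Parameters
    ----------
    F : (n, N) array
        Cumulative failure probabilities, row-wise non-decreasing.
    event_intervals : (n,) int array
        1-based observed interval per individual.
    c : (n,) int array
        Censoring indicator, 0 = event observed.
    """
    loss, _ = ranking_loss_with_grad(
        np.asarray(F, dtype=float), event_intervals, c, alpha=alpha, sigma=sigma
    )
    return loss


def ranking_loss_with_grad(
    F: np.ndarray,
    event_intervals: np.ndarray,
    c: np.ndarray,
    alpha: float = 0.1,
    sigma: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Loss plus gradient with respect to F (same shape)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    n = F.shape[0]
    k, c = _validate(n, event_intervals, c)
    dF = np.zeros_like(F)
    events = np.flatnonzero(c == 0)
    if events.size == 0:
        return 0.0, dF
    cols = k[events] - 1                      # event column per uncensored i
    Fcols = F[:, cols]                        # (n, n_events): F_j(t_i)
    Fii = F[events, cols]                     # F_i(t_i)
    acceptable = k[:, None] > k[events][None, :]   # j observed strictly later
    n_pairs = int(acceptable.sum())
    if n_pairs == 0:
        return 0.0, dF
    with np.errstate(over="ignore"):
        eta = np.exp(-(Fii[None, :] - Fcols) / sigma)
    eta = np.where(acceptable, eta, 0.0)
    scale = alpha / (n_pairs * sigma)
    loss = float(alpha * eta.sum() / n_pairs)
    # d/dF_j(t_i) = +scale * eta ; d/dF_i(t_i) = -scale * sum_j eta
    np.add.at(dF, (slice(None), cols), scale * eta)
    np.subtract.at(dF, (events, cols), scale * eta.sum(axis=0))
    return loss, dF


def ranking_grad_hazards(
    h: np.ndarray,
    event_intervals: np.ndarray,
    c: np.ndarray,
    alpha: float = 0.1,
    sigma: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Ranking loss and its gradient with respect to the hazards.

    Chains dL/dF through F[i,t] = 1 - prod_{s<=t}(1 - h[i,s]):
    dF[i,t]/dh[i,s] = S[i,t] / (1 - h[i,s]) for s <= t.
    """
    S = np.cumprod(1.0 - h, axis=1)
    F = 1.0 - S
    loss, dF = ranking_loss_with_grad(F, event_intervals, c, alpha=alpha, sigma=sigma)
    # reverse cumulative sum over t of dF * S, divided by (1 - h_s)
    rev = np.cumsum((dF * S)[:, ::-1], axis=1)[:, ::-1]
    dh = rev / np.clip(1.0 - h, _EPS, None)
    return loss, dh


def likelihood_loss(
    h: np.ndarray, event_intervals: np.ndarray, c: np.ndarray
) -> float:
    """Summed negative log-likelihood of a discrete-time hazard matrix."""
    loss, _ = likelihood_grad_hazards(h, event_intervals, c)
    return loss * h.shape[0]


def likelihood_grad_hazards(
    h: np.ndarray, event_intervals: np.ndarray, c: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-sample mean negative log-likelihood and gradient w.r.t. hazards."""
    h = np.asarray(h, dtype=float)
    n, N = h.shape
    k, c = _validate(n, event_intervals, c)
    rows = np.arange(n)
    cols = k - 1
    event = c == 0
    # mask of intervals contributing -log(1 - h): s < k for events, s <= k censored
    upto = cols + np.where(event, 0, 1)           # exclusive bound on s
    surv_mask = np.arange(N)[None, :] < upto[:, None]
    log1mh = np.log(np.clip(1.0 - h, _EPS, None))
    loss = -(surv_mask * log1mh).sum()
    loss += -(np.log(np.clip(h[rows[event], cols[event]], _EPS, None))).sum()
    dh = np.where(surv_mask, 1.0 / np.clip(1.0 - h, _EPS, None), 0.0)
    dh[rows[event], cols[event]] -= 1.0 / np.clip(h[rows[event], cols[event]], _EPS, None)
    return float(loss) / n, dh / n
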