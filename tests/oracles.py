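"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain per-element loops,
independent of the vectorised code paths in the package.
"""

from __future__ import annotations

import numpy as np


def survival_from_hazards_loop(h: np.ndarray) -> np.ndarray:
    n, N = h.shape
    S = np.empty_like(h)
    for i in range(n):
        prod = 1.0
        for t in range(N):
            prod *= 1.0 - h[i, t]
            S[i, t] = prod
    return S


def km_curve(times, events):
    """Product-limit estimate as (event_times, survival_values) via loops."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s = [], []
    prod = 1.0
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if d > 0:
            prod *= 1.0 - d / at_risk
            out_t.append(t)
            out_s.append(prod)
    return np.array(out_t), np.array(out_s)


def km_eval(event_times, survival, t, left=False):
    """Evaluate the step function; ``left`` gives the left limit S(t-)."""
    val = 1.0
    for et, s in zip(event_times, survival):
        if (et < t) if left else (et <= t):
            val = s
    return val


def harrell_oracle(scores, times, events):
    n = len(scores)
    conc = comp = 0.0
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[i] < times[j]:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


def antolini_oracle(S, intervals, events):
    n = len(intervals)
    conc = comp = 0.0
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if intervals[i] < intervals[j]:
                comp += 1
                si = S[i, intervals[i] - 1]
                sj = S[j, intervals[i] - 1]
                if si < sj:
                    conc += 1
                elif si == sj:
                    conc += 0.5
    return conc / comp


def brier_oracle(S_col, times, events, t_star):
    """Per-sample IPCW Brier computation with its own censoring KM."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    gt, gs = km_curve(times, ~events)
    total, used = 0.0, 0
    for i in range(len(times)):
        if events[i] and times[i] <= t_star:
            g = km_eval(gt, gs, times[i], left=True)
            if g <= 0:
                continue
            total += S_col[i] ** 2 / g
            used += 1
        elif times[i] > t_star:
            g = km_eval(gt, gs, t_star)
            if g <= 0:
                continue
            total += (1.0 - S_col[i]) ** 2 / g
            used += 1
        else:  # censored before t*: contributes 0 but counts
            used += 1
    return total / used


def ranking_oracle(F, intervals, c, alpha, sigma):
    """Brute-force double loop over ordered pairs with the acceptability rule."""
    n = F.shape[0]
    total, pairs = 0.0, 0
    for i in range(n):
        if c[i] != 0:
            continue
        for j in range(n):
            if intervals[i] < intervals[j]:
                pairs += 1
                total += np.exp(-(F[i, intervals[i] - 1] - F[j, intervals[i] - 1]) / sigma)
    if pairs == 0:
        return 0.0
    return alpha * total / pairs
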