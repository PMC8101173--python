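"""Jackknife pseudo-observations of survival and transformed smoothed curves.

The pseudo-observation of subject i at time t is
S_i(t) = n * S(t) - (n - 1) * S^{-i}(t), where S is the Kaplan–Meier
estimate on the full sample and S^{-i} the estimate after leaving subject i
out. Pseudo-values act as per-subject, per-time outcomes: smoothed against a
covariate and transformed (cloglog for the multiplicative family, scaled-log
for the additive family) they check the proportional-hazards/log-linearity
and constant-effect/linearity assumptions simultaneously.

The leave-one-out survival curves are computed by an exact incremental
formula (adjusting each product-limit factor for the removed subject's
at-risk status and event), which equals n independent Kaplan–Meier refits to
machine precision; the naive refit serves as the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox_mult import smooth_lowess
from .survdata import SurvivalDataError, SurvivalSample

CLAMP_EPS = 1e-6


@dataclass
class PseudoObsMatrix:
    """Per-subject jackknife pseudo-values on a time grid.

    ``values[i, j]`` is the pseudo-observation of subject i at
    ``times[j]``; ``km`` holds the full-sample Kaplan–Meier survival at the
    grid (the exact column mean of ``values``). Pseudo-values may lie
    outside [0, 1].
    """

    times: np.ndarray
    values: np.ndarray
    km: np.ndarray
    subject_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.times)


def pseudo_observations(sample: SurvivalSample, timegrid) -> PseudoObsMatrix:
    """Jackknife pseudo-observations S_i(t) = n S(t) - (n-1) S^{-i}(t).

    Exact incremental leave-one-out computation; ties in follow-up times are
    handled. Grid times should lie within the follow-up range.
    """
    n = sample.n
    if n < 2:
        raise SurvivalDataError("pseudo-observations require n >= 2")
    grid = np.asarray(timegrid, dtype=float)
    t, e = sample.times, sample.events

    # unique event times with death counts and at-risk counts
    ev_times = np.unique(t[e == 1])
    d = np.array([(e[t == tt] == 1).sum() for tt in ev_times], dtype=float)
    Y = np.array([(t >= tt).sum() for tt in ev_times], dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        f0 = 1.0 - d / Y                       # full-sample factors
        f1 = np.where(Y > 1, 1.0 - d / (Y - 1.0), 1.0)  # subject-at-risk, not event
    P0 = np.concatenate([[1.0], np.cumprod(f0)])  # P0[j] = prod of first j factors
    P1 = np.concatenate([[1.0], np.cumprod(f1)])

    # per subject: index of its own event time (or -1), own-time LOO factor
    own_idx = np.searchsorted(ev_times, t)
    at_event_time = (own_idx < ev_times.size) & np.isclose(
        ev_times[np.clip(own_idx, 0, max(ev_times.size - 1, 0))], t
    ) if ev_times.size else np.zeros(n, bool)
    f_own = np.ones(n)
    for i in range(n):
        if at_event_time[i]:
            k = own_idx[i]
            denom = Y[k] - 1.0
            num = d[k] - e[i]
            f_own[i] = 1.0 - num / denom if denom > 0 else 1.0

    values = np.empty((n, grid.size))
    km_grid = np.empty(grid.size)
    # number of event times strictly before each subject's own time
    n_before = np.searchsorted(ev_times, t, side="left")
    n_upto = np.searchsorted(ev_times, t, side="right")
    for j, tt in enumerate(grid):
        jg = np.searchsorted(ev_times, tt, side="right")  # events <= t
        km = P0[jg]
        km_grid[j] = km
        head = np.minimum(jg, n_before)          # events < T_i and <= tt
        own = (t <= tt) & at_event_time
        tail_from = n_upto                        # events after T_i start here
        with np.errstate(divide="ignore", invalid="ignore"):
            tail = np.where(
                jg > tail_from,
                _safe_ratio(P0, jg, tail_from, f0),
                1.0,
            )
        loo = P1[head] * np.where(own, f_own, 1.0) * tail
        values[:, j] = n * km - (n - 1) * loo
    return PseudoObsMatrix(times=grid, values=values, km=km_grid, subject_ids=sample.subject_ids)


def _safe_ratio(P0, jg, tail_from, f0):
    """P0[jg] / P0[tail_from] with explicit products where P0 hits zero."""
    denom = P0[tail_from]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, P0[jg] / np.where(denom > 0, denom, 1.0), np.nan)
    bad = np.flatnonzero(~np.isfinite(out) | (denom == 0))
    for i in bad:
        lo = int(tail_from[i]) if np.ndim(tail_from) else int(tail_from)
        out[i] = float(np.prod(f0[lo:jg]))
    return out


def event_time_deciles(sample: SurvivalSample) -> np.ndarray:
    """10%..90% empirical quantiles of the uncensored event times.

    Linear-interpolation quantiles (h = (n-1)p indexing). Duplicate grid
    values are collapsed with a warning; fewer than 10 events is an error.
    """
    ev = np.sort(sample.times[sample.events == 1])
    if ev.size < 10:
        raise SurvivalDataError("event-time deciles require at least 10 events")
    grid = np.quantile(ev, np.arange(1, 10) / 10.0, method="linear")
    uniq = np.unique(grid)
    if uniq.size < grid.size:
        if uniq.size < 2:
            raise SurvivalDataError("degenerate event-time grid: all deciles identical")
        warnings.warn("duplicate event-time deciles collapsed", stacklevel=2)
    return uniq


@dataclass
class EffectCurves:
    """Transformed smoothed pseudo-observation curves at each grid time."""

    transform: str
    times: np.ndarray
    x: np.ndarray                  # common (sorted) covariate support
    curves: np.ndarray             # (n_times, len(x)) transformed smooths
    slopes: np.ndarray             # least-squares slope of each curve
    linearity_scores: np.ndarray   # max |curve - secant| / range per curve
    parallelism_score: float       # dispersion of pairwise slope differences
    clamp_count: int               # smoothed values clamped into (0, 1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "slope": self.slopes, "linearity": self.linearity_scores}
        )


def covariate_effect_curves(
    pseudo: PseudoObsMatrix,
    covariate,
    transform: str = "cloglog",
) -> EffectCurves:
    """Smooth pseudo-values against a continuous covariate, then transform.

    For each grid time the pseudo-values are lowess-smoothed against the
    covariate first, clamped into [eps, 1-eps] (eps = 1e-6, counted), then
    transformed: ``cloglog`` gives log(-log s) (linear in z with slope beta
    under a log-linear proportional-hazards model), ``scaled_log`` gives
    -log(s)/t (linear in z with slope gamma under a constant additive
    model). Per-curve linearity and cross-curve parallelism scores are
    advisory operationalizations of the visual judgement.
    """
    if transform not in ("cloglog", "scaled_log"):
        raise ValueError("transform must be 'cloglog' or 'scaled_log'")
    x = np.asarray(covariate, dtype=float)
    curves, slopes, lins = [], [], []
    clamped = 0
    xs_ref = None
    for j, tt in enumerate(pseudo.times):
        # no robustness iterations: extreme pseudo-values (outside [0, 1] or
        # exactly 0/1 before any censoring) are genuine, not outliers, and
        # robust reweighting would discard the minority outcome wholesale
        xs, sm = smooth_lowess(pseudo.values[:, j], x, it=0)
        clip = (sm < CLAMP_EPS) | (sm > 1 - CLAMP_EPS)
        clamped += int(clip.sum())
        sm = np.clip(sm, CLAMP_EPS, 1 - CLAMP_EPS)
        if transform == "cloglog":
            cur = np.log(-np.log(sm))
        else:
            cur = -np.log(sm) / tt
        xs_ref = xs
        curves.append(cur)
        # slope and linearity on the clamp-free region only: the transform is
        # saturated (hence uninformative) where the smooth left (0, 1)
        keep = ~clip if (~clip).sum() >= 3 else np.ones_like(clip)
        xk, ck = xs[keep], cur[keep]
        A = np.vstack([np.ones_like(xk), xk]).T
        coef, *_ = np.linalg.lstsq(A, ck, rcond=None)
        slopes.append(coef[1])
        secant = ck[0] + (ck[-1] - ck[0]) * (xk - xk[0]) / max(xk[-1] - xk[0], 1e-300)
        rng = np.ptp(ck)
        lins.append(float(np.max(np.abs(ck - secant)) / rng) if rng > 0 else 0.0)
    slopes = np.asarray(slopes)
    if slopes.size > 1:
        diffs = np.abs(slopes[:, None] - slopes[None, :])
        parallelism = float(diffs[np.triu_indices(slopes.size, k=1)].mean())
    else:
        parallelism = 0.0
    return EffectCurves(
        transform=transform,
        times=pseudo.times,
        x=xs_ref,
        curves=np.vstack(curves),
        slopes=slopes,
        linearity_scores=np.asarray(lins),
        parallelism_score=parallelism,
        clamp_count=clamped,
    )
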