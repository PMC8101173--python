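"""Survival-data containers, file I/O and nonparametric estimators.

The module houses the two data representations used throughout the package:

* :class:`SurvivalSample` — one row per subject with a right-censored
  follow-up time, an event indicator and covariates;
* :class:`CountingProcessSample` — the episode-split ``(start, stop]``
  counting-process representation that makes time-by-covariate interaction
  terms ordinary columns.

plus :class:`StepFunction` (right-continuous step functions over time,
housing Kaplan–Meier, Nelson–Aalen, Breslow and cumulative-regression
estimates), tie jittering and episode splitting.

Conventions: the time origin is 0, episodes are half-open intervals
``(start, stop]`` and a subject is at risk at time ``t`` when its follow-up
time is ``>= t`` (left-continuous at-risk process) — in particular a subject
is at risk at its own event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, NelsonAalenFitter
from lifelines.utils import median_survival_times


class SurvivalDataError(ValueError):
    """Raised when survival data violate a structural invariant."""


# ---------------------------------------------------------------------------
# Step functions
# ---------------------------------------------------------------------------


class StepFunction:
    """Right-continuous step function over time.

    Parameters
    ----------
    jump_times
        Strictly increasing jump locations.
    values
        Function value *after* each jump (same length as ``jump_times``).
    value_at_origin
        Value on ``[0, jump_times[0])``. Defaults to 0 (cumulative hazards);
        survival functions use 1.
    """

    def __init__(
        self,
        jump_times: Sequence[float],
        values: Sequence[float],
        value_at_origin: float = 0.0,
    ) -> None:
        jt = np.asarray(jump_times, dtype=float)
        vals = np.asarray(values, dtype=float)
        if jt.ndim != 1 or vals.shape != jt.shape:
            raise SurvivalDataError("jump_times and values must be 1-d and equal length")
        if jt.size and np.any(np.diff(jt) <= 0):
            raise SurvivalDataError("jump_times must be strictly increasing")
        self.jump_times = jt
        self.values = vals
        self.value_at_origin = float(value_at_origin)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            out = np.full(t.shape, self.value_at_origin)
            return out if out.ndim else float(self.value_at_origin)
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        out = np.where(idx < 0, self.value_at_origin, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StepFunction({self.jump_times.size} jumps, origin={self.value_at_origin})"


class SurvivalFunction(StepFunction):
    """Kaplan–Meier style survival curve with median and its CI."""

    def __init__(self, jump_times, values, median, median_ci):
        super().__init__(jump_times, values, value_at_origin=1.0)
        #: first time with S(t) <= 0.5 (inf when the curve never reaches 0.5)
        self.median = float(median)
        #: log(-log)-transform based confidence interval for the median
        self.median_ci = (float(median_ci[0]), float(median_ci[1]))


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

_RESERVED = ("subject_id", "time", "event")


@dataclass
class SurvivalSample:
    """Subject-level right-censored survival data with covariates.

    ``df`` has columns ``subject_id``, ``time``, ``event`` plus one numeric
    column per covariate. ``covariate_info`` records, per covariate, whether
    it is numeric, binary, or a dummy derived from a categorical column (in
    which case the reference level is recorded).
    """

    df: pd.DataFrame
    covariate_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_survival_frame(self.df)
        for c in self.covariates:
            if c not in self.covariate_info:
                self.covariate_info[c] = _infer_covariate_info(self.df[c])

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def covariates(self) -> list:
        return [c for c in self.df.columns if c not in _RESERVED]

    def covariate(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def is_binary(self, name: str) -> bool:
        return self.covariate_info.get(name, {}).get("kind") in ("binary", "dummy")

    def subset(self, mask) -> "SurvivalSample":
        return SurvivalSample(self.df.loc[np.asarray(mask)].copy(), dict(self.covariate_info))

    def with_columns(self, cols: pd.DataFrame) -> "SurvivalSample":
        """Return a copy with extra (e.g. transformed) covariate columns."""
        df = pd.concat([self.df, cols.reset_index(drop=True)], axis=1)
        return SurvivalSample(df, dict(self.covariate_info))

    def to_counting_process(self) -> "CountingProcessSample":
        df = self.df.copy()
        df.insert(1, "start", 0.0)
        df = df.rename(columns={"time": "stop", "event": "status"})
        return CountingProcessSample(df, dict(self.covariate_info))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class CountingProcessSample:
    """Episode-split counting-process data: ``(start, stop]`` intervals.

    Invariants: episodes of one subject are contiguous, non-overlapping and
    ordered; at most the final episode of a subject carries ``status = 1``.
    """

    df: pd.DataFrame
    covariate_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_counting_frame(self.df)

    @property
    def n_episodes(self) -> int:
        return len(self.df)

    @property
    def covariates(self) -> list:
        return [c for c in self.df.columns if c not in ("subject_id", "start", "stop", "status")]

    def collapse(self) -> SurvivalSample:
        """Merge each subject's episodes back into a single follow-up row."""
        last = self.df.groupby("subject_id", sort=False).tail(1).reset_index(drop=True)
        ev = self.df.groupby("subject_id", sort=False)["status"].sum().to_numpy()
        out = last.drop(columns=["start"]).rename(columns={"stop": "time", "status": "event"})
        out["event"] = ev.astype(int)
        return SurvivalSample(out, dict(self.covariate_info))


def _infer_covariate_info(col: pd.Series) -> dict:
    vals = set(pd.unique(col.dropna()))
    if vals <= {0, 1, 0.0, 1.0}:
        return {"kind": "binary"}
    return {"kind": "numeric"}


def _validate_survival_frame(df: pd.DataFrame) -> None:
    for c in _RESERVED:
        if c not in df.columns:
            raise SurvivalDataError(f"missing required column '{c}'")
    t = df["time"].to_numpy()
    if not np.issubdtype(np.asarray(t).dtype, np.number) or np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise SurvivalDataError("all times must be strictly positive and finite")
    ev = df["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise SurvivalDataError("event indicator must be 0 or 1 for every row")
    if df["subject_id"].duplicated().any():
        raise SurvivalDataError("exactly one row per subject is required")
    cov = [c for c in df.columns if c not in _RESERVED]
    if df[cov].isna().any().any():
        bad = [c for c in cov if df[c].isna().any()]
        raise SurvivalDataError(f"missing covariate values in columns: {bad}")
    for c in cov:
        if not np.issubdtype(df[c].dtype, np.number):
            raise SurvivalDataError(f"covariate column '{c}' is not numeric after encoding")


def _validate_counting_frame(df: pd.DataFrame) -> None:
    for c in ("subject_id", "start", "stop", "status"):
        if c not in df.columns:
            raise SurvivalDataError(f"missing required column '{c}'")
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    status = df["status"].to_numpy()
    if np.any(start >= stop):
        raise SurvivalDataError("episodes require start < stop")
    if not np.isin(status, [0, 1]).all():
        raise SurvivalDataError("status must be 0 or 1")
    codes, uniques = pd.factorize(df["subject_id"])
    if len(codes) > 1:
        same = codes[1:] == codes[:-1]
        if np.sum(~same) + 1 != len(uniques):
            raise SurvivalDataError("episodes of each subject must be consecutive rows")
        if np.any(same & ~np.isclose(start[1:], stop[:-1])):
            raise SurvivalDataError("episodes of a subject must be contiguous and ordered")
        # a status=1 episode must be its subject's last
        if np.any((status[:-1] == 1) & same):
            raise SurvivalDataError("only the final episode of a subject may have status=1")
    if np.any(np.bincount(codes, weights=status) > 1):
        raise SurvivalDataError("at most one event per subject")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_survival_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> SurvivalSample:
    """Read a subject-level survival table from CSV.

    ``column_map`` maps the canonical names ``id``, ``time``, ``event`` to the
    file's column names (identity by default); remaining columns become
    covariates. Categorical (non-numeric) covariates are dummy-encoded with
    the first-observed level as reference, recorded in ``covariate_info``.
    """
    raw = pd.read_csv(path, sep=delimiter)
    cmap = {"id": "id", "time": "time", "event": "event"}
    if column_map:
        cmap.update(column_map)
    for canonical, name in cmap.items():
        if name not in raw.columns:
            raise SurvivalDataError(f"column '{name}' (mapped to '{canonical}') not found in {path}")
    df = raw.rename(
        columns={cmap["id"]: "subject_id", cmap["time"]: "time", cmap["event"]: "event"}
    )
    info: dict = {}
    for c in list(df.columns):
        if c in _RESERVED:
            continue
        if df[c].isna().any():
            raise SurvivalDataError(f"missing values in covariate column '{c}'")
        if not np.issubdtype(df[c].dtype, np.number):
            levels = list(pd.unique(df[c]))
            ref = levels[0]
            for lev in levels[1:]:
                newc = f"{c}_{lev}"
                df[newc] = (df[c] == lev).astype(float)
                info[newc] = {"kind": "dummy", "source": c, "level": lev, "reference": ref}
            df = df.drop(columns=[c])
    return SurvivalSample(df, info)


def read_counting_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> CountingProcessSample:
    """Read an episode-split counting-process table (id,start,stop,status,...)."""
    raw = pd.read_csv(path, sep=delimiter)
    cmap = {"id": "id", "start": "start", "stop": "stop", "status": "status"}
    if column_map:
        cmap.update(column_map)
    for canonical, name in cmap.items():
        if name not in raw.columns:
            raise SurvivalDataError(f"column '{name}' (mapped to '{canonical}') not found in {path}")
    df = raw.rename(
        columns={
            cmap["id"]: "subject_id",
            cmap["start"]: "start",
            cmap["stop"]: "stop",
            cmap["status"]: "status",
        }
    )
    return CountingProcessSample(df)


# ---------------------------------------------------------------------------
# Risk sets and nonparametric estimators
# ---------------------------------------------------------------------------


def risk_set(sample: SurvivalSample, t: float) -> np.ndarray:
    """Subjects at risk at ``t``: ``{i : time_i >= t}``.

    A subject is at risk at its own event (or censoring) time.
    """
    if t <= 0:
        raise SurvivalDataError("risk sets are defined for t > 0")
    return sample.subject_ids[sample.times >= t]


def kaplan_meier(sample: SurvivalSample) -> SurvivalFunction:
    """Product-limit survival estimator with median and log(-log)-based CI."""
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, sample.events)
    ev_times = np.unique(sample.times[sample.events == 1])
    surv = kmf.survival_function_at_times(ev_times).to_numpy() if ev_times.size else np.array([])
    median = kmf.median_survival_time_
    try:
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    except Exception:  # no events
        lo = hi = np.inf
    return SurvivalFunction(ev_times, surv, median, (lo, hi))


def nelson_aalen(sample: SurvivalSample) -> StepFunction:
    """Nelson–Aalen cumulative hazard: sum of d_j / Y_j over event times."""
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(sample.times, sample.events)
    ev_times = np.unique(sample.times[sample.events == 1])
    if ev_times.size == 0:
        return StepFunction([], [], 0.0)
    vals = naf.cumulative_hazard_.loc[ev_times].to_numpy().ravel()
    return StepFunction(ev_times, vals, 0.0)


# ---------------------------------------------------------------------------
# Tie jittering and episode splitting
# ---------------------------------------------------------------------------


def jitter_ties(
    sample: SurvivalSample, seed: int, scale: float | None = None
) -> SurvivalSample:
    """Break tied follow-up times by adding Uniform(0, scale) noise.

    The default scale is 1e-6 times the maximum time; it must be smaller than
    half the minimum gap between distinct times so the ordering of originally
    distinct times is preserved. Reproducible given ``seed``.
    """
    t = sample.times
    distinct = np.unique(t)
    min_gap = np.min(np.diff(distinct)) if distinct.size > 1 else np.inf
    if scale is None:
        scale = 1e-6 * float(np.max(t))
        if np.isfinite(min_gap):
            scale = min(scale, 0.49 * min_gap)
    if scale <= 0:
        raise SurvivalDataError("jitter scale must be > 0")
    if scale >= min_gap / 2.0:
        raise SurvivalDataError(
            f"jitter scale {scale} too large to preserve ordering (min gap {min_gap})"
        )
    rng = np.random.default_rng(seed)
    for _ in range(100):
        jt = t + rng.uniform(0.0, scale, size=t.size)
        if np.unique(jt).size == t.size:
            df = sample.df.copy()
            df["time"] = jt
            return SurvivalSample(df, dict(sample.covariate_info))
    raise SurvivalDataError("could not produce unique times")  # pragma: no cover


def split_episodes(
    sample: SurvivalSample, cutpoints: Iterable[float]
) -> CountingProcessSample:
    """Partition each subject's ``(0, time]`` interval at interior cutpoints.

    The event status is carried by the final episode only; covariates are
    copied into every episode. An empty cutpoint list (or cutpoints beyond
    the maximum follow-up) yields one episode per subject.
    """
    cuts = np.asarray(sorted(set(cutpoints)), dtype=float)
    if cuts.size and (np.any(cuts <= 0) or np.any(~np.isfinite(cuts))):
        raise SurvivalDataError("cutpoints must be strictly positive and finite")
    rows = []
    cov = sample.covariates
    for _, row in sample.df.iterrows():
        t = float(row["time"])
        interior = cuts[cuts < t]
        bounds = np.concatenate([[0.0], interior, [t]])
        for j in range(len(bounds) - 1):
            rec = {
                "subject_id": row["subject_id"],
                "start": bounds[j],
                "stop": bounds[j + 1],
                "status": int(row["event"]) if j == len(bounds) - 2 else 0,
            }
            for c in cov:
                rec[c] = row[c]
            rows.append(rec)
    return CountingProcessSample(pd.DataFrame(rows), dict(sample.covariate_info))
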