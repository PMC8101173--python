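"""Multiplicative-hazards core.

Cox partial-likelihood estimation on counting-process data — plain, or
extended with time-varying coefficients beta(t) and non-log-linear
functional forms f(x) — together with the diagnostics the fitting strategy
relies on: Schoenfeld and martingale residuals, the proportional-hazards
correlation test, AIC, functional-form scans and breakpoint scans.

Model: lambda_i(t | x_i) = lambda_0(t) * exp( sum_c f_c(x_ic) * beta_c(t) ),
with beta_c(t) expanded on a small basis (constant; beta0 + beta1*t;
beta0 + beta1*t + beta2*(t-c)*I(t>c)). A covariate with a time-varying
basis contributes one design column per basis function, evaluated at each
event time inside the partial likelihood — mathematically identical to
episode-splitting at all distinct event times, without materialising the
split data.

Estimation is Newton–Raphson on the log partial likelihood (Efron tie
correction, identical to Breslow when event times are unique), starting at
zero, tolerance 1e-9 on the score sup-norm, step-halving on likelihood
decrease. The covariance is the inverse observed information and the
baseline cumulative hazard is the Breslow estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .survdata import (
    CountingProcessSample,
    StepFunction,
    SurvivalDataError,
    SurvivalSample,
)

#: lowess settings used for every residual smooth in the package
LOWESS_FRAC = 2.0 / 3.0
LOWESS_IT = 3

NR_TOL = 1e-9
NR_MAX_ITER = 50
NR_MAX_HALVINGS = 30


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


class DegenerateDesignError(ValueError):
    """A design column is constant within every risk set."""


def smooth_lowess(y, x, frac: float = LOWESS_FRAC, it: int = LOWESS_IT):
    """Lowess smooth of y against x; returns (x_sorted, fitted)."""
    out = _sm_lowess(np.asarray(y, float), np.asarray(x, float), frac=frac, it=it)
    return out[:, 0], out[:, 1]


# ---------------------------------------------------------------------------
# Functional forms and time-varying bases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionalForm:
    """Functional form f(x) of a continuous covariate.

    kind:
      - ``identity``: x itself
      - ``scaled_exponential``: exp(x / c) with scaling constant ``c``
      - ``polynomial``: one column per power in ``powers`` (e.g. [1, 2])
      - ``fractional_polynomial``: powers from {-2,-1,-0.5,0,0.5,1,2,3},
        power 0 meaning log(x); requires x > 0
      - ``spline``: truncated-power cubic basis with interior ``knots``
      - ``piecewise_threshold``: columns of ``base`` plus the base form
        applied to (x - cutoff), active only where x > cutoff
    """

    kind: str = "identity"
    c: float = 1.0
    powers: tuple = ()
    knots: tuple = ()
    cutoff: float | None = None
    base: "FunctionalForm | None" = None

    _FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

    def columns(self, x: np.ndarray, name: str) -> pd.DataFrame:
        """Evaluate the form on observed values; deterministic and finite."""
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            out = {name: x}
        elif self.kind == "scaled_exponential":
            out = {f"exp({name}/{self.c:g})": np.exp(x / self.c)}
        elif self.kind == "polynomial":
            out = {f"{name}^{p:g}": x**p for p in self.powers}
        elif self.kind == "fractional_polynomial":
            bad = [p for p in self.powers if p not in self._FP_POWERS]
            if bad:
                raise ValueError(f"fractional polynomial powers {bad} not allowed")
            out = {}
            for p in self.powers:
                out[f"{name}^{p:g}" if p != 0 else f"log({name})"] = (
                    np.log(x) if p == 0 else x**p
                )
        elif self.kind == "spline":
            out = {f"{name}": x, f"{name}^2": x**2, f"{name}^3": x**3}
            for k in self.knots:
                out[f"({name}-{k:g})+^3"] = np.clip(x - k, 0.0, None) ** 3
        elif self.kind == "piecewise_threshold":
            base = self.base or FunctionalForm("identity")
            out = dict(base.columns(x, name))
            gate = (x > self.cutoff).astype(float)
            sup = base.columns(x - self.cutoff, f"({name}-{self.cutoff:g})")
            for cname, col in sup.items():
                out[f"{cname}*({name}>{self.cutoff:g})"] = np.where(gate > 0, col, 0.0)
        else:
            raise ValueError(f"unknown functional form kind '{self.kind}'")
        df = pd.DataFrame(out)
        if not np.isfinite(df.to_numpy()).all():
            raise FloatingPointError(f"form {self.label} non-finite on observed range")
        return df

    @property
    def label(self) -> str:
        if self.kind == "identity":
            return "identity"
        if self.kind == "scaled_exponential":
            return f"exp(x/{self.c:g})"
        if self.kind == "polynomial":
            return "poly(" + ",".join(f"{p:g}" for p in self.powers) + ")"
        if self.kind == "fractional_polynomial":
            return "fp(" + ",".join(f"{p:g}" for p in self.powers) + ")"
        if self.kind == "spline":
            return "spline(" + ",".join(f"{k:g}" for k in self.knots) + ")"
        if self.kind == "piecewise_threshold":
            return f"{(self.base or FunctionalForm()).label}+cutoff@{self.cutoff:g}"
        return self.kind  # pragma: no cover

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "c": self.c, "powers": list(self.powers), "knots": list(self.knots), "cutoff": self.cutoff}
        if self.base is not None:
            d["base"] = self.base.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FunctionalForm":
        base = cls.from_dict(d["base"]) if d.get("base") else None
        return cls(
            kind=d.get("kind", "identity"),
            c=d.get("c", 1.0),
            powers=tuple(d.get("powers") or ()),
            knots=tuple(d.get("knots") or ()),
            cutoff=d.get("cutoff"),
            base=base,
        )


@dataclass(frozen=True)
class TimeVaryingSpec:
    """Time-varying coefficient basis for one covariate.

    ``constant`` contributes one coefficient, ``linear`` two
    (beta0 + beta1*t) and ``linear_with_break`` three
    (beta0 + beta1*t + beta2*(t - break_time) * I(t > break_time)).
    """

    basis: str = "constant"
    break_time: float | None = None

    def basis_functions(self, name: str) -> list:
        if self.basis == "constant":
            return [(name, lambda t: np.ones_like(t))]
        if self.basis == "linear":
            return [(name, lambda t: np.ones_like(t)), (f"{name}:t", lambda t: t)]
        if self.basis == "linear_with_break":
            c = self.break_time
            if c is None:
                raise ValueError("linear_with_break requires break_time")
            return [
                (name, lambda t: np.ones_like(t)),
                (f"{name}:t", lambda t: t),
                (f"{name}:(t-{c:g})+", lambda t: np.clip(t - c, 0.0, None)),
            ]
        raise ValueError(f"unknown basis '{self.basis}'")

    @property
    def n_coefficients(self) -> int:
        return {"constant": 1, "linear": 2, "linear_with_break": 3}[self.basis]

    def to_dict(self) -> dict:
        return {"basis": self.basis, "break_time": self.break_time}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TimeVaryingSpec":
        return cls(basis=d.get("basis", "constant"), break_time=d.get("break_time"))


# ---------------------------------------------------------------------------
# Partial-likelihood engine
# ---------------------------------------------------------------------------


class _CoxEngine:
    """Evaluates the partial likelihood, score and information on
    counting-process episodes with design columns that may depend on time."""

    def __init__(self, data: CountingProcessSample, design: Sequence[str],
                 time_varying: Mapping[str, TimeVaryingSpec] | None = None):
        df = data.df
        self.start = df["start"].to_numpy(dtype=float)
        self.stop = df["stop"].to_numpy(dtype=float)
        self.status = df["status"].to_numpy(dtype=int)
        self.subject_id = df["subject_id"].to_numpy()
        time_varying = dict(time_varying or {})
        for c in list(design) + list(time_varying):
            if c not in df.columns:
                raise SurvivalDataError(f"design column '{c}' not in data")
        static_cols = [c for c in design if c not in time_varying]
        self.names: list[str] = list(static_cols)
        self._static = (
            df[static_cols].to_numpy(dtype=float)
            if static_cols
            else np.empty((len(df), 0))
        )
        self._tv: list[tuple[np.ndarray, Callable]] = []
        for c in design:
            if c in time_varying:
                vals = df[c].to_numpy(dtype=float)
                for bname, bf in time_varying[c].basis_functions(c):
                    self.names.append(bname)
                    self._tv.append((vals, bf))
        self.p = len(self.names)
        if self.status.sum() < 1:
            raise SurvivalDataError("at least one event is required")
        self._index_events()

    def _index_events(self) -> None:
        ev_times = np.unique(self.stop[self.status == 1])
        self.event_times = ev_times
        self.risk_idx: list[np.ndarray] = []
        self.death_pos: list[np.ndarray] = []  # positions of deaths inside risk set
        self.Z: list[np.ndarray] = []
        for t in ev_times:
            ridx = np.flatnonzero((self.start < t) & (self.stop >= t))
            dmask = (self.stop[ridx] == t) & (self.status[ridx] == 1)
            self.risk_idx.append(ridx)
            self.death_pos.append(np.flatnonzero(dmask))
            if self.p:
                parts = [self._static[ridx]]
                for vals, bf in self._tv:
                    parts.append((vals[ridx] * bf(np.asarray(t))).reshape(-1, 1))
                self.Z.append(np.ascontiguousarray(np.hstack(parts)))
            else:
                self.Z.append(np.empty((ridx.size, 0)))
        # stacked layout for the vectorized single-death path
        self._all_single = all(d.size == 1 for d in self.death_pos)
        if self._all_single and self.p:
            counts = np.array([z.shape[0] for z in self.Z])
            self._offs = np.concatenate([[0], np.cumsum(counts)[:-1]])
            self._bigZ = np.vstack(self.Z)
            self._death_rows = self._offs + np.array([d[0] for d in self.death_pos])

    # -- likelihood / score / information (Efron ties) ----------------------
    def evaluate(self, beta: np.ndarray, order: int = 2):
        # the stacked path wins while call overhead dominates; per-event BLAS
        # wins once the stacked risk sets outgrow cache
        if (
            self.p
            and self._all_single
            and self.p <= 12
            and self._bigZ.shape[0] <= 400_000
        ):
            return self._evaluate_single(beta, order)
        return self._evaluate_loop(beta, order)

    def _evaluate_single(self, beta: np.ndarray, order: int):
        """Vectorized path for unique event times (Efron == Breslow)."""
        p = self.p
        offs = self._offs
        eta = self._bigZ @ beta
        shift = np.maximum.reduceat(eta, offs)
        counts = np.diff(np.append(offs, eta.size))
        w = np.exp(eta - np.repeat(shift, counts))
        s0 = np.add.reduceat(w, offs)
        ll = float(eta[self._death_rows].sum() - np.log(s0).sum() - shift.sum())
        score = np.zeros(p)
        info = np.zeros((p, p))
        if order >= 1:
            wz = w[:, None] * self._bigZ
            s1 = np.add.reduceat(wz, offs, axis=0)
            m1 = s1 / s0[:, None]
            score = self._bigZ[self._death_rows].sum(axis=0) - m1.sum(axis=0)
            if order >= 2:
                # contiguous 1-d segment sums per coefficient pair
                zcols = [np.ascontiguousarray(self._bigZ[:, b]) for b in range(p)]
                wzcols = [w * zc for zc in zcols]
                for a in range(p):
                    for b in range(a, p):
                        s2 = np.add.reduceat(wzcols[a] * zcols[b], offs)
                        v = float((s2 / s0 - m1[:, a] * m1[:, b]).sum())
                        info[a, b] = v
                        info[b, a] = v
        return ll, score, info

    def _evaluate_loop(self, beta: np.ndarray, order: int = 2):
        p = self.p
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for Z, dpos in zip(self.Z, self.death_pos):
            eta = Z @ beta if p else np.zeros(Z.shape[0])
            shift = eta.max()
            w = np.exp(eta - shift)
            d = dpos.size
            s0 = w.sum()
            ll += float(eta[dpos].sum())
            if p:
                s1 = w @ Z
                Zd = Z[dpos]
                wd = w[dpos]
                d0 = wd.sum()
                d1 = wd @ Zd
            else:
                d0 = w[dpos].sum()
            frac = np.arange(d) / d
            phi = s0 - frac * d0  # length d
            ll -= float(np.log(phi).sum()) + d * shift
            if order >= 1 and p:
                m1 = (s1[None, :] - frac[:, None] * d1[None, :]) / phi[:, None]
                score += Zd.sum(axis=0) - m1.sum(axis=0)
                if order >= 2:
                    s2 = Z.T @ (w[:, None] * Z)
                    d2 = Zd.T @ (wd[:, None] * Zd)
                    for l in range(d):
                        a2 = (s2 - frac[l] * d2) / phi[l]
                        info += a2 - np.outer(m1[l], m1[l])
        return ll, score, info

    def loglik(self, beta: np.ndarray) -> float:
        return self.evaluate(np.asarray(beta, dtype=float), order=0)[0]

    def fit(self, initial_beta=None, max_iter: int = NR_MAX_ITER, tol: float = NR_TOL):
        beta = np.zeros(self.p) if initial_beta is None else np.asarray(initial_beta, float).copy()
        ll, score, info = self.evaluate(beta)
        if max_iter == 0:
            return beta, ll, score, info
        for _ in range(max_iter):
            if self.p == 0 or np.max(np.abs(score)) < tol:
                break
            if np.linalg.cond(info) > 1e12:
                raise DegenerateDesignError(
                    "singular information matrix: a design column is constant "
                    "within every risk set (or columns are collinear)"
                )
            step = np.linalg.solve(info, score)
            new_beta = beta + step
            new_ll, new_score, new_info = self.evaluate(new_beta)
            halvings = 0
            ll_slack = 1e-9 * (1.0 + abs(ll))  # float plateau near the optimum
            while new_ll < ll - ll_slack and np.max(np.abs(new_score)) >= tol:
                halvings += 1
                if halvings > NR_MAX_HALVINGS:
                    raise ConvergenceError(
                        "partial likelihood failed to increase (monotone likelihood?)"
                    )
                step /= 2.0
                new_beta = beta + step
                new_ll, new_score, new_info = self.evaluate(new_beta)
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
            if np.max(np.abs(beta)) > 500:
                raise ConvergenceError("divergent coefficients (monotone likelihood)")
        else:
            if np.max(np.abs(score)) >= tol:
                raise ConvergenceError("Newton-Raphson did not converge")
        if self.p and max_iter > 0:
            n_events = sum(d.size for d in self.death_pos)
            if np.linalg.eigvalsh(info).min() < 1e-6 * n_events:
                if np.max(np.abs(beta)) < 1.0:
                    raise DegenerateDesignError(
                        "flat partial likelihood: a design column is constant "
                        "within every risk set (or columns are collinear)"
                    )
                raise ConvergenceError(
                    "vanishing information at the optimum: monotone likelihood "
                    "(divergent coefficient)"
                )
        return beta, ll, score, info

    # -- quantities at a fixed beta -----------------------------------------
    def baseline_increments(self, beta: np.ndarray) -> np.ndarray:
        """Breslow increments d_j / sum_{risk} exp(z'beta), one per event time."""
        inc = np.empty(self.event_times.size)
        for j, (Z, dpos) in enumerate(zip(self.Z, self.death_pos)):
            eta = Z @ beta if self.p else np.zeros(Z.shape[0])
            shift = eta.max()
            inc[j] = dpos.size * np.exp(-shift) / np.exp(eta - shift).sum()
        return inc

    def schoenfeld(self, beta: np.ndarray):
        """One residual row per event: z_event - weighted risk-set mean."""
        times, ranks, rows = [], [], []
        tie_rank = stats.rankdata(
            np.concatenate([np.full(d.size, t) for t, d in zip(self.event_times, self.death_pos)])
        )
        k = 0
        for t, Z, dpos in zip(self.event_times, self.Z, self.death_pos):
            eta = Z @ beta if self.p else np.zeros(Z.shape[0])
            w = np.exp(eta - eta.max())
            zbar = (w @ Z) / w.sum() if self.p else np.zeros(0)
            for dp in dpos:
                times.append(t)
                ranks.append(tie_rank[k])
                rows.append(Z[dp] - zbar)
                k += 1
        resid = pd.DataFrame(rows, columns=self.names)
        resid.insert(0, "rank", np.asarray(ranks))
        resid.insert(0, "time", np.asarray(times))
        return resid

    def cumulative_intensity(self, beta: np.ndarray) -> np.ndarray:
        """Per-subject estimated cumulative intensity int Y_i exp(z_i'beta) dLambda0."""
        inc = self.baseline_increments(beta)
        ep = np.zeros(self.start.size)
        for j, (ridx, Z) in enumerate(zip(self.risk_idx, self.Z)):
            eta = Z @ beta if self.p else np.zeros(Z.shape[0])
            ep[ridx] += inc[j] * np.exp(eta)
        out = pd.Series(ep).groupby(pd.Series(self.subject_id)).sum()
        return out

    def stratum_intensity_paths(self, beta: np.ndarray, labels_by_subject: Mapping):
        """Expected cumulative events per stratum at each event time, and the
        per-subject martingale increment structure needed for resampling."""
        inc = self.baseline_increments(beta)
        lab = np.asarray([labels_by_subject[s] for s in self.subject_id])
        groups = np.unique(lab)
        expected = {g: np.zeros(self.event_times.size) for g in groups}
        for j, (ridx, Z) in enumerate(zip(self.risk_idx, self.Z)):
            eta = Z @ beta if self.p else np.zeros(Z.shape[0])
            contrib = inc[j] * np.exp(eta)
            lg = lab[ridx]
            for g in groups:
                expected[g][j] = contrib[lg == g].sum()
        for g in groups:
            expected[g] = np.cumsum(expected[g])
        return expected


def _as_counting(data) -> CountingProcessSample:
    if isinstance(data, SurvivalSample):
        return data.to_counting_process()
    if isinstance(data, CountingProcessSample):
        return data
    raise TypeError("expected SurvivalSample or CountingProcessSample")


# ---------------------------------------------------------------------------
# Fitted-model container and residuals
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted (possibly extended) Cox model."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n_params: int
    baseline: StepFunction
    design: list
    time_varying: dict
    data: CountingProcessSample = field(repr=False)
    _engine: _CoxEngine = field(repr=False)
    converged: bool = True

    @property
    def k(self) -> int:
        return self.n_params

    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())), index=self.coefficients.index)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Coefficient table: coef, HR, Wald CI and p-value."""
        se = self.standard_errors()
        z = self.coefficients / se
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": se,
                "hr": np.exp(self.coefficients),
                "hr_lower": np.exp(self.coefficients - q * se),
                "hr_upper": np.exp(self.coefficients + q * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclass
class ResidualSet:
    """Schoenfeld residuals (one row per event) and/or martingale residuals
    (one value per subject), with a lowess-smoothing helper."""

    schoenfeld: pd.DataFrame | None = None
    martingale: pd.Series | None = None

    def smooth_martingale(self, covariate_values) -> tuple[np.ndarray, np.ndarray]:
        """Lowess smooth of martingale residuals against a continuous covariate."""
        if self.martingale is None:
            raise ValueError("no martingale residuals in this set")
        return smooth_lowess(self.martingale.to_numpy(), covariate_values)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fit_cox(
    data,
    design: Sequence[str],
    time_varying: Mapping[str, TimeVaryingSpec] | None = None,
    initial_beta=None,
    max_iter: int = NR_MAX_ITER,
) -> CoxFit:
    """Maximize the Cox partial likelihood on counting-process data.

    ``design`` lists covariate columns; covariates named in ``time_varying``
    are expanded on the requested beta(t) basis. ``max_iter=0`` evaluates the
    model at ``initial_beta`` without iterating (useful for diagnostics at a
    fixed coefficient value).
    """
    cp = _as_counting(data)
    eng = _CoxEngine(cp, design, time_varying)
    beta, ll, score, info = eng.fit(initial_beta=initial_beta, max_iter=max_iter)
    if eng.p:
        if max_iter == 0:
            # diagnostic evaluation at a fixed beta; covariance best-effort
            cov = np.linalg.pinv(info)
        else:
            if np.linalg.cond(info) > 1e12:
                raise DegenerateDesignError("information matrix is singular at the optimum")
            cov = np.linalg.inv(info)
        cov = (cov + cov.T) / 2.0
    else:
        cov = np.zeros((0, 0))
    inc = eng.baseline_increments(beta)
    baseline = StepFunction(eng.event_times, np.cumsum(inc), 0.0)
    return CoxFit(
        coefficients=pd.Series(beta, index=eng.names),
        covariance=pd.DataFrame(cov, index=eng.names, columns=eng.names),
        loglik=ll,
        n_params=eng.p,
        baseline=baseline,
        design=list(design),
        time_varying={k: v for k, v in (time_varying or {}).items()},
        data=cp,
        _engine=eng,
        converged=max_iter > 0,
    )


def fit_cox_null(data) -> CoxFit:
    """Null Cox model (no covariates): Breslow baseline is Nelson–Aalen."""
    return fit_cox(data, design=[])


def partial_loglik(data, design: Sequence[str], beta,
                   time_varying: Mapping[str, TimeVaryingSpec] | None = None) -> float:
    """Log partial likelihood at a supplied coefficient vector."""
    eng = _CoxEngine(_as_counting(data), design, time_varying)
    return eng.loglik(np.asarray(beta, dtype=float))


def schoenfeld_residuals(fit: CoxFit) -> ResidualSet:
    """Per-event residuals r_j = z_(j) - weighted risk-set mean at beta-hat."""
    return ResidualSet(schoenfeld=fit._engine.schoenfeld(fit.coefficients.to_numpy()))


def martingale_residuals(fit: CoxFit) -> ResidualSet:
    """Per-subject residuals m_i = d_i - Lambda0(T_i) * exp(z_i' beta).

    For the null model this reduces to d_i minus the Nelson–Aalen estimate at
    the subject's follow-up time. Residuals sum to zero at the fitted
    coefficients (Breslow-baseline score identity).
    """
    eng = fit._engine
    intensity = eng.cumulative_intensity(fit.coefficients.to_numpy())
    events = (
        pd.Series(eng.status).groupby(pd.Series(eng.subject_id)).sum().astype(float)
    )
    m = events - intensity
    # restore input subject order
    order = pd.unique(eng.subject_id)
    return ResidualSet(martingale=m.loc[order])


def ph_test(fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """Proportional-hazards test per design column.

    Pearson correlation between the (unscaled) Schoenfeld residuals and the
    rank order of event times, with its two-sided t-test p-value; the
    assumption is called satisfied when p > alpha. Columns whose residuals
    are identically zero are degenerate and reported as satisfied with p = 1.
    """
    res = schoenfeld_residuals(fit).schoenfeld
    if len(res) < 3:
        raise SurvivalDataError("PH test requires at least 3 events")
    ranks = res["rank"].to_numpy()
    rows = {}
    for col in fit.coefficients.index:
        r = res[col].to_numpy()
        if np.ptp(r) == 0 or np.ptp(ranks) == 0:
            corr, p = 0.0, 1.0
        else:
            corr, p = stats.pearsonr(r, ranks)
        rows[col] = {"correlation": corr, "p": p, "satisfied": p > alpha}
    return pd.DataFrame(rows).T


def aic(fit: CoxFit) -> float:
    """Akaike information criterion: -2 * loglik + 2 * n_params."""
    return -2.0 * fit.loglik + 2.0 * fit.n_params


def functional_form_scan(
    sample: SurvivalSample,
    covariate: str,
    candidates: Sequence[FunctionalForm],
) -> pd.DataFrame:
    """Fit each candidate functional form univariately and rank by AIC.

    The flatness score is the maximum absolute deviation of the lowess smooth
    of the fitted model's martingale residuals (against the untransformed
    covariate) from its mean — near-horizontal smooths mark good candidates;
    AIC decides. Candidates producing non-finite transforms are skipped with
    a warning entry (aic = NaN).
    """
    if len(candidates) < 2:
        raise ValueError("at least 2 candidate forms are required")
    x = sample.covariate(covariate)
    records = []
    for form in candidates:
        try:
            cols = form.columns(x, covariate)
        except (FloatingPointError, ValueError) as exc:
            records.append(
                {"form": form, "label": form.label, "aic": np.nan, "flatness": np.nan,
                 "n_params": np.nan, "skipped": str(exc)}
            )
            continue
        aug = sample.with_columns(cols.add_prefix("_ff_"))
        names = [f"_ff_{c}" for c in cols.columns]
        fit = fit_cox(aug, names)
        _, sm = martingale_residuals(fit).smooth_martingale(x)
        records.append(
            {"form": form, "label": form.label, "aic": aic(fit),
             "flatness": float(np.max(np.abs(sm - sm.mean()))),
             "n_params": fit.n_params, "skipped": ""}
        )
    out = pd.DataFrame(records).sort_values("aic", na_position="last").reset_index(drop=True)
    return out


def breakpoint_scan(
    sample: SurvivalSample,
    covariate: str,
    grid: Sequence[float],
    design: Sequence[str] | None = None,
    time_varying: Mapping[str, TimeVaryingSpec] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Scan break times for a linear-with-break beta(t) on ``covariate``.

    For each grid point c the model with basis beta0 + beta1*t +
    beta2*(t-c)I(t>c) is fitted and its AIC recorded; returns the argmin
    (ties broken toward smaller c) and the full profile. Grid points with no
    events on one side are skipped.
    """
    design = list(design) if design is not None else [covariate]
    tv = dict(time_varying or {})
    ev = np.sort(sample.times[sample.events == 1])
    rows = []
    for c in grid:
        if not (ev.min() <= c < ev.max()) or not np.any(ev > c) or not np.any(ev <= c):
            rows.append({"break_time": c, "aic": np.nan, "skipped": "no events on one side"})
            continue
        tv_c = dict(tv)
        tv_c[covariate] = TimeVaryingSpec("linear_with_break", break_time=float(c))
        try:
            fit = fit_cox(sample, design, time_varying=tv_c)
            rows.append({"break_time": c, "aic": aic(fit), "skipped": ""})
        except (ConvergenceError, DegenerateDesignError) as exc:
            rows.append({"break_time": c, "aic": np.nan, "skipped": str(exc)})
    profile = pd.DataFrame(rows)
    valid = profile.dropna(subset=["aic"])
    if valid.empty:
        raise SurvivalDataError("no admissible break time in the grid")
    best = valid.sort_values(["aic", "break_time"]).iloc[0]
    return float(best["break_time"]), profile
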