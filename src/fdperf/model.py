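"""Nonlinear (mixed-effects) models predicting performance from alertness,
circadian phase, wake duration, and sleep debt.

The response ``P`` (log mean PVT reaction time, ADD correct, or DSST correct)
is modelled as a function of a composite predictor

    X = A + b6*cos(C + b7) + b8*T

where ``A`` is subjective alertness (VAS, 0-100), ``C`` circadian phase in
degrees (0 deg at the fitted melatonin maximum), ``T`` hours since scheduled
wake, and ``W`` cumulative sleep debt in hours.  Three model forms share
this predictor, differing in how phase and wake duration saturate:

    linear:       P = b1 + (b2*W + b3) * X
    exponential:  P = b1 + (b2*W + b3) * exp(b4*X)
    logistic:     P = b1 + (b2*W + b3) * sigmoid(b4 + b5*X)

Any of the four explanatory variables can be excluded by pinning its
coefficient to zero (alertness drops the ``A`` term from ``X``); sweeping
all 16 subsets and comparing AIC ranks the variables by predictive value.

Fitting is nonlinear least squares with a Gaussian residual model.  The
parameters entering linearly (b1, b2, b3) are profiled out by variable
projection, so the optimizer only searches the few genuinely nonlinear
parameters; the circadian term is fitted in the linear ``bc*cos C + bs*sin C``
parameterization and reported as amplitude/phase ``(b6 >= 0, b7 in [0,360))``.
Mixed-effects fits place subject random effects on a configurable subset of
(b1, b2, b3) and alternate a first-order linearization with a linear
mixed-model step (statsmodels ``MixedLM``, ML).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

__all__ = [
    "VARIABLES",
    "FORMS",
    "ModelSpec",
    "composite_X",
    "predict",
    "PerformanceModel",
    "PerformanceResults",
    "aic_sweep",
    "prediction_error_summary",
    "fit_subset_ls",
]

VARIABLES = ("alertness", "phase", "wake_duration", "sleep_debt")
FORMS = ("linear", "exponential", "logistic")
PARAM_NAMES = ("b1", "b2", "b3", "b4", "b5", "b6", "b7", "b8")

#: bound on the exponent in the exponential form (and in X products) to keep
#: intermediate values finite during optimization
EXP_CLIP = 50.0


def _check_include(include: Sequence[str]) -> frozenset:
    inc = frozenset(include)
    unknown = inc - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables in include: {sorted(unknown)}")
    return inc


@dataclass(frozen=True)
class ModelSpec:
    """Model form, variable-inclusion mask, and parameter values b1-b8.

    Excluded variables carry a coefficient of exactly zero: excluding
    phase forces b6 = 0, wake_duration forces b8 = 0, sleep_debt forces
    b2 = 0, and excluding alertness drops A from X (coefficient 0 instead
    of the fixed 1 it has when included).
    """

    form: str
    include: frozenset = frozenset(VARIABLES)
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        object.__setattr__(self, "include", _check_include(self.include))
        p = {name: 0.0 for name in PARAM_NAMES}
        p.update(self.params)
        extra = set(self.params) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)}")
        if "phase" not in self.include:
            p["b6"] = 0.0
        if "wake_duration" not in self.include:
            p["b8"] = 0.0
        if "sleep_debt" not in self.include:
            p["b2"] = 0.0
        object.__setattr__(self, "params", p)


def composite_X(A, C, T, params: Mapping[str, float],
                include: Sequence[str] = VARIABLES) -> np.ndarray:
    """Composite predictor X = A + b6*cos(C + b7) + b8*T (C, b7 in degrees).

    The alertness term enters with a fixed coefficient of 1 when included
    and 0 when excluded.
    """
    inc = _check_include(include)
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(C)) and np.all(np.isfinite(T))):
        raise ValueError("composite_X inputs must be finite")
    a_coef = 1.0 if "alertness" in inc else 0.0
    b6 = params.get("b6", 0.0)
    b7 = params.get("b7", 0.0)
    b8 = params.get("b8", 0.0)
    return a_coef * A + b6 * np.cos(np.radians(C + b7)) + b8 * T


def _link(form: str, X, b4: float, b5: float):
    X = np.asarray(X, dtype=float)
    if form == "linear":
        return X
    if form == "exponential":
        return np.exp(np.clip(b4 * X, -EXP_CLIP, EXP_CLIP))
    return expit(np.clip(b4 + b5 * X, -EXP_CLIP, EXP_CLIP))


def predict(spec: ModelSpec, X, W) -> np.ndarray:
    """Predicted response for composite predictor X and sleep debt W.

    linear: b1 + (b2 W + b3) X; exponential: b1 + (b2 W + b3) e^{b4 X}
    (exponent clipped at +/-50); logistic: b1 + (b2 W + b3) sigmoid(b4 + b5 X),
    using the numerically stable sigmoid.
    """
    p = spec.params
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    gain = p["b2"] * W + p["b3"]
    return p["b1"] + gain * _link(spec.form, X, p["b4"], p["b5"])


def predict_records(spec: ModelSpec, A, C, T, W) -> np.ndarray:
    """Convenience: composite_X then predict."""
    X = composite_X(A, C, T, spec.params, spec.include)
    return predict(spec, X, W)


# --------------------------------------------------------------------------
# internal parameterization of the free parameters for each (form, include)

@dataclass(frozen=True)
class _Parameterization:
    """Free-parameter layout for one (form, include) combination.

    ``lin`` lists parameters entering linearly (profiled by variable
    projection); ``nl`` the genuinely nonlinear ones the optimizer searches.
    When alertness is excluded, the scale of X is unidentified against the
    gain/link, so one parameter is pinned (linear: b3=1, exponential: b4=1,
    logistic: b5=1).  When X has no terms at all the model collapses to an
    intercept (plus a W slope for the exponential/logistic forms when
    sleep debt is included).
    """

    form: str
    include: frozenset
    lin: tuple[str, ...]      # subset of (b1, b2, b3)
    nl: tuple[str, ...]       # subset of (b4, b5, bc, bs, b8)
    fixed: Mapping[str, float]

    @property
    def n_free(self) -> int:
        return len(self.lin) + len(self.nl)


def _parameterization(form: str, include: frozenset) -> _Parameterization:
    has_a = "alertness" in include
    has_c = "phase" in include
    has_t = "wake_duration" in include
    has_w = "sleep_debt" in include
    x_terms = has_a or has_c or has_t

    fixed = {"b2": 0.0, "b3": 0.0, "b4": 0.0, "b5": 0.0,
             "bc": 0.0, "bs": 0.0, "b8": 0.0}
    lin: list[str] = ["b1"]
    nl: list[str] = []

    if not x_terms:
        # X == 0: linear form is an intercept; exponential/logistic collapse
        # to intercept + W slope when sleep debt is included
        if has_w and form != "linear":
            lin.append("b2")
        if form == "logistic":
            # report a definite curve: sigmoid(0) = 1/2 absorbed into b2
            pass
        par = _Parameterization(form, include, tuple(lin), (), dict(fixed))
        return par

    if form == "linear":
        if has_a:
            lin.append("b3")
        else:
            fixed["b3"] = 1.0
    else:
        lin.append("b3")
    if has_w:
        lin.append("b2")

    if form == "exponential":
        if has_a:
            nl.append("b4")
        else:
            fixed["b4"] = 1.0
    elif form == "logistic":
        nl.append("b4")
        if has_a:
            nl.append("b5")
        else:
            fixed["b5"] = 1.0
    if has_c:
        nl.extend(["bc", "bs"])
    if has_t:
        nl.append("b8")
    return _Parameterization(form, include, tuple(lin), tuple(nl), fixed)


def _nl_dict(par: _Parameterization, theta_nl: np.ndarray) -> dict[str, float]:
    d = dict(par.fixed)
    for name, val in zip(par.nl, theta_nl):
        d[name] = float(val)
    return d


class _Objective:
    """Variable-projection residuals for one dataset and parameterization."""

    def __init__(self, par: _Parameterization, y, A, C, T, W):
        self.par = par
        self.y = np.asarray(y, float)
        self.A = np.asarray(A, float)
        self.cosC = np.cos(np.radians(np.asarray(C, float)))
        self.sinC = np.sin(np.radians(np.asarray(C, float)))
        self.T = np.asarray(T, float)
        self.W = np.asarray(W, float)
        self.a_coef = 1.0 if "alertness" in par.include else 0.0

    def _X(self, d: Mapping[str, float]) -> np.ndarray:
        return (self.a_coef * self.A + d["bc"] * self.cosC
                + d["bs"] * self.sinC + d["b8"] * self.T)

    def link(self, d: Mapping[str, float]) -> np.ndarray:
        return _link(self.par.form, self._X(d), d["b4"], d["b5"])

    def _columns(self, L: np.ndarray) -> dict[str, np.ndarray]:
        ones = np.ones_like(self.y)
        return {"b1": ones, "b2": self.W * L, "b3": L}

    def profile(self, theta_nl: np.ndarray):
        """Solve the linear subproblem; return (lin coef dict, residuals)."""
        d = _nl_dict(self.par, theta_nl)
        L = self.link(d)
        cols = self._columns(L)
        offset = np.zeros_like(self.y)
        for name in ("b2", "b3"):
            if name not in self.par.lin and self.par.fixed.get(name, 0.0) != 0.0:
                offset = offset + self.par.fixed[name] * cols[name]
        D = np.column_stack([cols[name] for name in self.par.lin])
        target = self.y - offset
        coef, *_ = np.linalg.lstsq(D, target, rcond=None)
        resid = target - D @ coef
        lin = dict(zip(self.par.lin, coef.tolist()))
        return lin, resid

    def residuals(self, theta_nl: np.ndarray) -> np.ndarray:
        return self.profile(theta_nl)[1]

    def full_params(self, theta_nl: np.ndarray) -> dict[str, float]:
        """Reported b1-b8 from a nonlinear point (profiling the linear part)."""
        lin, _ = self.profile(theta_nl)
        d = _nl_dict(self.par, theta_nl)
        out = {"b1": 0.0, "b2": 0.0, "b3": self.par.fixed.get("b3", 0.0),
               "b4": d["b4"], "b5": d["b5"], "b8": d["b8"]}
        out.update(lin)
        bc, bs = d["bc"], d["bs"]
        out["b6"] = math.hypot(bc, bs)
        out["b7"] = math.degrees(math.atan2(-bs, bc)) % 360.0 if out["b6"] > 0 else 0.0
        return out


def _starts(obj: _Objective, n_starts: int, seed: int) -> list[np.ndarray]:
    """Data-driven starts plus Latin-hypercube draws over documented boxes."""
    par = obj.par
    if not par.nl:
        return [np.zeros(0)]
    y, A = obj.y, obj.A
    dy = float(np.ptp(y)) or 1.0
    x0 = A if obj.a_coef else obj.cosC + obj.T
    dx = float(np.ptp(x0)) or 1.0
    xmid = float(np.median(x0))
    corr = float(np.corrcoef(x0, y)[0, 1]) if np.std(x0) > 0 else -1.0
    sgn = -1.0 if corr < 0 else 1.0

    boxes = {
        "b4": (-8.0, 8.0) if par.form == "logistic" else (-4.0 / dx, 4.0 / dx),
        "b5": (-16.0 / dx, 16.0 / dx),
        "bc": (-0.4 * dx, 0.4 * dx),
        "bs": (-0.4 * dx, 0.4 * dx),
        "b8": (-2.0, 2.0),
    }
    lo = np.array([boxes[n][0] for n in par.nl])
    hi = np.array([boxes[n][1] for n in par.nl])

    starts: list[np.ndarray] = []
    for flip in (1.0, -1.0):
        guess = {"b4": 0.0, "b5": 0.0, "bc": 0.0, "bs": 0.0, "b8": 0.0}
        if par.form == "logistic":
            b5 = flip * sgn * 8.0 / dx
            if "b5" in par.nl:
                guess["b5"] = b5
                guess["b4"] = -b5 * xmid
            else:  # b5 pinned at 1: steer with b4 only
                guess["b4"] = -xmid
        elif par.form == "exponential":
            if "b4" in par.nl:
                guess["b4"] = flip * sgn * 2.0 / dx
        starts.append(np.array([guess[n] for n in par.nl]))
    n_lhs = max(n_starts - len(starts), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(par.nl), seed=seed)
        u = sampler.random(n_lhs)
        starts.extend(lo + u * (hi - lo))
    return starts[:max(n_starts, 1)]


# --------------------------------------------------------------------------
# results container


@dataclass
class PerformanceResults:
    """Fitted performance model: estimates, fit statistics, diagnostics.

    Attributes
    ----------
    spec : ModelSpec
        Model form, inclusion mask, and the fitted parameter values; usable
        directly with :func:`predict`.
    bse : dict
        Approximate standard errors of the free parameters (Gauss-Newton,
        Gaussian residual model).
    random_effects : dict | None
        Per-subject offsets keyed by participant id (mixed fits only).
    re_sd : dict | None
        Estimated random-effect standard deviations by parameter name.
    loglik, aic, adj_r2 : float
        Gaussian log-likelihood (marginal and first-order approximate for
        mixed fits), 2k - 2*loglik, and adjusted R^2 (conditional residuals
        for mixed fits).
    """

    spec: ModelSpec
    method: str                    # "fixed" | "mixed"
    bse: dict
    loglik: float
    aic: float
    adj_r2: float
    n_obs: int
    n_params: int
    converged: bool
    sigma: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    random_effects: dict | None = None
    re_sd: dict | None = None
    free_names: tuple[str, ...] = ()

    @property
    def params(self) -> dict[str, float]:
        return dict(self.spec.params)

    @property
    def rss(self) -> float:
        return float(np.dot(self.resid, self.resid))

    def predict(self, A, C, T, W) -> np.ndarray:
        """Population-level (fixed-effect) predictions on new data."""
        return predict_records(self.spec, A, C, T, W)

    def to_dict(self) -> dict:
        return {
            "form": self.spec.form,
            "include": sorted(self.spec.include),
            "method": self.method,
            "params": {k: float(v) for k, v in self.spec.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "adj_r2": float(self.adj_r2),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "sigma": float(self.sigma),
            "re_sd": {k: float(v) for k, v in self.re_sd.items()} if self.re_sd else None,
        }

    def summary(self) -> str:
        lines = [
            f"{'Performance model results':^62}",
            "=" * 62,
            f"Form:          {self.spec.form:<20} Method:    {self.method}",
            f"N obs:         {self.n_obs:<20} N params:  {self.n_params}",
            f"Log-lik:       {self.loglik:<20.3f} AIC:       {self.aic:.1f}",
            f"Adj. R2:       {self.adj_r2:<20.4f} sigma:     {self.sigma:.4f}",
            f"Included:      {', '.join(sorted(self.spec.include)) or '(none)'}",
            f"Converged:     {self.converged}",
            "-" * 62,
            f"{'param':>6} {'estimate':>14} {'std err':>12}",
        ]
        for name in PARAM_NAMES:
            se = self.bse.get(name)
            se_s = f"{se:12.4g}" if se is not None else f"{'--':>12}"
            lines.append(f"{name:>6} {self.spec.params[name]:14.6g} {se_s}")
        if self.re_sd:
            lines.append("-" * 62)
            for k, v in self.re_sd.items():
                lines.append(f"  random-effect SD on {k}: {v:.4g}")
        lines.append("=" * 62)
        return "\n".join(lines)


# --------------------------------------------------------------------------
# the model object


class PerformanceModel:
    """Nonlinear performance model bound to a paired-session dataset.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format observations with columns ``P`` (response), ``A``
        (alertness 0-100), ``C`` (phase, degrees), ``T`` (hours since wake),
        ``W`` (sleep debt, hours), and ``participant_id``.
    form : str
        "linear", "exponential", or "logistic".
    include : sequence of str
        Variables kept in the model (subset of alertness, phase,
        wake_duration, sleep_debt).  Excluded variables get coefficient 0.
    """

    REQUIRED = ("P", "A", "C", "T", "W")

    def __init__(self, data: pd.DataFrame, form: str = "logistic",
                 include: Sequence[str] = VARIABLES):
        if form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        self.form = form
        self.include = _check_include(include)
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"data missing columns: {missing}")
        sub = data.dropna(subset=list(self.REQUIRED)).reset_index(drop=True)
        vals = sub[list(self.REQUIRED)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite values in model data")
        if np.any((sub["C"] < 0) | (sub["C"] >= 360)):
            raise ValueError("C must lie in [0, 360)")
        self.data = sub
        self.groups = (sub["participant_id"].astype(str).to_numpy()
                       if "participant_id" in sub.columns
                       else np.zeros(len(sub), dtype=str))
        self._par = _parameterization(form, self.include)
        self._obj = _Objective(self._par, sub["P"], sub["A"], sub["C"],
                               sub["T"], sub["W"])

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, response: str = "pvt",
                   **kwargs) -> "PerformanceModel":
        """Build from a paired-sessions table (see :mod:`fdperf.pairing`).

        For ``response="pvt"`` the modelled quantity is the natural log of
        the session mean reaction time; ADD/DSST correct counts are used
        untransformed.
        """
        sub = pairs[pairs["objective_kind"] == response].copy()
        if sub.empty:
            raise ValueError(f"no paired sessions of kind {response!r}")
        if response == "pvt":
            if np.any(sub["value"] <= 0):
                raise ValueError("PVT session means must be positive")
            sub["P"] = np.log(sub["value"].astype(float))
        else:
            sub["P"] = sub["value"].astype(float)
        return cls(sub, **kwargs)

    # -- fixed effects ----------------------------------------------------

    def fit(self, n_starts: int = 20, seed: int = 0,
            method: str = "fixed",
            random_effects: Sequence[str] = ("b1", "b3"),
            max_iter: int = 12) -> PerformanceResults:
        """Fit by (mixed-effects) nonlinear least squares.

        Multi-start: a pair of data-driven initial points plus Latin-
        hypercube draws over documented parameter boxes, ``n_starts`` total;
        the best final objective is kept.  ``method="mixed"`` adds subject
        random effects on the parameters named in ``random_effects``
        (subset of b1, b2, b3).
        """
        if method not in ("fixed", "mixed"):
            raise ValueError("method must be 'fixed' or 'mixed'")
        fixed = self._fit_fixed(n_starts=n_starts, seed=seed)
        if method == "fixed":
            return fixed
        return self._fit_mixed(fixed, random_effects, max_iter=max_iter)

    def _fit_fixed(self, n_starts: int, seed: int) -> PerformanceResults:
        obj = self._obj
        par = self._par
        n = len(obj.y)
        if n < par.n_free + 2:
            raise ValueError(
                f"need at least {par.n_free + 2} observations, got {n}")
        best = None
        best_theta = None
        best_ok = False
        for theta0 in _starts(obj, n_starts, seed):
            if par.nl:
                try:
                    sol = optimize.least_squares(
                        obj.residuals, theta0, method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                cost, theta, ok = sol.cost, sol.x, bool(sol.status > 0)
            else:
                r = obj.residuals(theta0)
                cost, theta, ok = 0.5 * float(r @ r), theta0, True
            if best is None or cost < best - 1e-12:
                best, best_theta, best_ok = cost, theta, ok
        if best_theta is None:
            raise RuntimeError("all optimizer starts failed")
        return self._package_fixed(best_theta, best_ok)

    def _package_fixed(self, theta_nl: np.ndarray, converged: bool) -> PerformanceResults:
        obj, par = self._obj, self._par
        reported = obj.full_params(theta_nl)
        spec = ModelSpec(self.form, self.include, reported)
        lin, resid = obj.profile(theta_nl)
        n = len(obj.y)
        k_mean = par.n_free
        sigma2 = float(resid @ resid) / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = k_mean + 1  # + residual variance
        aic = 2 * k - 2 * loglik if converged else float("inf")
        fitted = obj.y - resid
        adj = adjusted_r2_from_resid(obj.y, resid, k_mean)
        bse = self._bse(theta_nl, sigma2)
        free_names = tuple(par.lin) + tuple(par.nl)
        return PerformanceResults(
            spec=spec, method="fixed", bse=bse, loglik=loglik, aic=aic,
            adj_r2=adj, n_obs=n, n_params=k, converged=converged,
            sigma=math.sqrt(sigma2), fittedvalues=fitted, resid=resid,
            free_names=free_names)

    def _free_vector(self, theta_nl: np.ndarray) -> np.ndarray:
        lin, _ = self._obj.profile(theta_nl)
        return np.array([lin[n] for n in self._par.lin] + list(theta_nl))

    def _mean_jacobian(self, theta_free: np.ndarray):
        """Fitted values and Jacobian d fitted / d (lin + nl params)."""
        obj, par = self._obj, self._par
        nlin = len(par.lin)
        lin_vals = theta_free[:nlin]
        theta_nl = theta_free[nlin:]
        d = _nl_dict(par, theta_nl)
        L = obj.link(d)
        cols = obj._columns(L)
        D = np.column_stack([cols[n] for n in par.lin])
        offset = np.zeros_like(obj.y)
        for name in ("b2", "b3"):
            if name not in par.lin and par.fixed.get(name, 0.0) != 0.0:
                offset = offset + par.fixed[name] * cols[name]
        fitted = offset + D @ lin_vals

        def fitted_of_nl(t):
            dd = _nl_dict(par, t)
            LL = obj.link(dd)
            cc = obj._columns(LL)
            off = np.zeros_like(obj.y)
            for name in ("b2", "b3"):
                if name not in par.lin and par.fixed.get(name, 0.0) != 0.0:
                    off = off + par.fixed[name] * cc[name]
            DD = np.column_stack([cc[n] for n in par.lin])
            return off + DD @ lin_vals

        Jnl = []
        for j in range(len(theta_nl)):
            h = 1e-6 * max(1.0, abs(theta_nl[j]))
            tp = theta_nl.copy(); tp[j] += h
            tm = theta_nl.copy(); tm[j] -= h
            Jnl.append((fitted_of_nl(tp) - fitted_of_nl(tm)) / (2 * h))
        J = np.column_stack([D] + Jnl) if Jnl else D
        return fitted, J, L

    def _bse(self, theta_nl: np.ndarray, sigma2: float) -> dict:
        par = self._par
        theta_free = self._free_vector(theta_nl)
        _, J, _ = self._mean_jacobian(theta_free)
        try:
            cov = sigma2 * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(theta_free), np.nan)
        names = list(par.lin) + list(par.nl)
        out = dict(zip(names, se.tolist()))
        # map internal (bc, bs) onto reported amplitude/phase by the delta
        # method would require the full covariance; report them raw instead
        return out

    # -- mixed effects ----------------------------------------------------

    def _fit_mixed(self, fixed: PerformanceResults,
                   random_effects: Sequence[str],
                   max_iter: int = 12) -> PerformanceResults:
        import statsmodels.api as sm

        obj, par = self._obj, self._par
        re_names = tuple(random_effects)
        bad = set(re_names) - {"b1", "b2", "b3"}
        if bad:
            raise ValueError(
                f"random effects supported on b1, b2, b3 only; got {sorted(bad)}")
        x_empty = not (self.include & {"alertness", "phase", "wake_duration"})
        if x_empty:
            # X == 0: the b3 (and for linear, b2) random-effect columns are
            # constant and collinear with the intercept
            re_names = ("b1",)
        groups = self.groups
        ids = pd.unique(groups)
        if len(ids) < 2:
            raise ValueError("mixed fit needs at least 2 subjects")

        # start from the fixed fit; reconstruct internal bc/bs from b6/b7
        b6, b7 = fixed.spec.params["b6"], fixed.spec.params["b7"]
        d = {"bc": b6 * math.cos(math.radians(b7)),
             "bs": -b6 * math.sin(math.radians(b7))}
        theta_nl = np.array([fixed.spec.params[n] if n in ("b4", "b5", "b8")
                             else d[n] for n in par.nl])
        theta = self._free_vector(theta_nl)

        md_fit = None
        converged = False
        for it in range(max_iter):
            fitted, J, L = self._mean_jacobian(theta)
            w = obj.y - fitted + J @ theta
            zcols = {"b1": np.ones_like(obj.y), "b2": obj.W * L, "b3": L}
            Z = np.column_stack([zcols[n] for n in re_names])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.regression.mixed_linear_model.MixedLM(
                    w, J, groups=groups, exog_re=Z)
                try:
                    md_fit = md.fit(reml=False, method="lbfgs", maxiter=200)
                except (np.linalg.LinAlgError, ValueError):
                    break
            theta_new = np.asarray(md_fit.fe_params)
            step = theta_new - theta
            theta = theta + step
            if np.linalg.norm(step) <= 1e-8 * (1 + np.linalg.norm(theta)):
                converged = True
                break
        if md_fit is None:
            warnings.warn("mixed fit failed; returning fixed-effects fit")
            return fixed

        cov_re = np.asarray(md_fit.cov_re)
        sigma2 = float(md_fit.scale)
        re_var = np.diag(cov_re)
        if np.any(re_var < 1e-10 * max(sigma2, 1e-12)):
            warnings.warn(
                "singular random-effect variance; refitting as fixed effects")
            return fixed

        nlin = len(par.lin)
        theta_nl_fin = theta[nlin:]
        lin_fin = dict(zip(par.lin, theta[:nlin].tolist()))
        dnl = _nl_dict(par, theta_nl_fin)
        reported = {"b1": 0.0, "b2": 0.0, "b3": par.fixed.get("b3", 0.0),
                    "b4": dnl["b4"], "b5": dnl["b5"], "b8": dnl["b8"]}
        reported.update(lin_fin)
        reported["b6"] = math.hypot(dnl["bc"], dnl["bs"])
        reported["b7"] = (math.degrees(math.atan2(-dnl["bs"], dnl["bc"])) % 360.0
                          if reported["b6"] > 0 else 0.0)
        spec = ModelSpec(self.form, self.include, reported)

        fitted, J, L = self._mean_jacobian(theta)
        zcols = {"b1": np.ones_like(obj.y), "b2": obj.W * L, "b3": L}
        Z = np.column_stack([zcols[n] for n in re_names])
        re_by_subject = {}
        cond_fitted = fitted.copy()
        for gid, u in md_fit.random_effects.items():
            mask = groups == gid
            uvec = np.asarray(u)
            re_by_subject[str(gid)] = dict(zip(re_names, uvec.tolist()))
            cond_fitted[mask] = fitted[mask] + Z[mask] @ uvec
        resid = obj.y - cond_fitted

        n = len(obj.y)
        k_mean = par.n_free
        q = len(re_names)
        k = k_mean + 1 + q * (q + 1) // 2
        loglik = float(md_fit.llf)  # marginal, first-order linearization
        aic = 2 * k - 2 * loglik
        adj = adjusted_r2_from_resid(obj.y, resid, k_mean)
        re_sd = {n_: float(math.sqrt(max(v, 0.0)))
                 for n_, v in zip(re_names, re_var)}
        bse = dict(zip(list(par.lin) + list(par.nl),
                       np.asarray(md_fit.bse_fe).tolist()))
        return PerformanceResults(
            spec=spec, method="mixed", bse=bse, loglik=loglik, aic=aic,
            adj_r2=adj, n_obs=n, n_params=k, converged=converged,
            sigma=math.sqrt(sigma2), fittedvalues=cond_fitted, resid=resid,
            random_effects=re_by_subject, re_sd=re_sd,
            free_names=tuple(par.lin) + tuple(par.nl))


def adjusted_r2_from_resid(y: np.ndarray, resid: np.ndarray, n_mean_params: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).

    ``p`` counts estimated mean-structure parameters beyond the intercept,
    so an intercept-only model scores ~0 and a perfect fit scores 1.
    """
    y = np.asarray(y, float)
    resid = np.asarray(resid, float)
    n = len(y)
    p = max(n_mean_params - 1, 0)
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares")
    r2 = 1.0 - float(resid @ resid) / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def aic_sweep(data: pd.DataFrame, form: str = "logistic",
              method: str = "fixed",
              random_effects: Sequence[str] = ("b1", "b3"),
              n_starts: int = 8, seed: int = 0) -> pd.DataFrame:
    """Fit all 16 variable subsets and tabulate AIC and adjusted R^2.

    Returns one row per subset (including the empty set) with columns
    ``include`` (comma-joined label), one boolean column per variable,
    ``aic``, ``adj_r2``, ``converged``, ``n_params``.  Non-converged fits
    carry ``aic = +inf``.  Rows come back sorted by AIC.
    """
    from itertools import combinations

    rows = []
    for r in range(len(VARIABLES) + 1):
        for subset in combinations(VARIABLES, r):
            model = PerformanceModel(data, form=form, include=subset)
            try:
                res = model.fit(n_starts=n_starts, seed=seed, method=method,
                                random_effects=random_effects)
                row = {
                    "include": ",".join(subset) if subset else "(none)",
                    **{v: (v in subset) for v in VARIABLES},
                    "aic": res.aic, "adj_r2": res.adj_r2,
                    "converged": res.converged, "n_params": res.n_params,
                }
            except (RuntimeError, ValueError) as exc:
                row = {
                    "include": ",".join(subset) if subset else "(none)",
                    **{v: (v in subset) for v in VARIABLES},
                    "aic": float("inf"), "adj_r2": float("nan"),
                    "converged": False, "n_params": 0,
                }
            rows.append(row)
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    return out


def prediction_error_summary(results: PerformanceResults,
                             data: pd.DataFrame) -> pd.DataFrame:
    """Per-participant under/over-estimation of PVT session means, in ms.

    The response is log mean reaction time, so predictions are
    back-transformed with ``exp``.  Underestimation means the model
    predicted a faster session than observed (observed - predicted > 0).
    Returns max and SD of the under- and over-estimates per participant.
    """
    if data.empty:
        raise ValueError("no paired sessions to summarize")
    pred_ms = np.exp(results.fittedvalues)
    obs_ms = np.exp(np.asarray(data["P"], float))
    err = obs_ms - pred_ms  # >0: model underestimated the reaction time
    frame = pd.DataFrame({
        "participant_id": data["participant_id"].astype(str).to_numpy(),
        "err": err,
    })
    rows = []
    for pid, g in frame.groupby("participant_id", sort=True):
        under = g["err"][g["err"] > 0]
        over = -g["err"][g["err"] < 0]
        rows.append({
            "participant_id": pid,
            "max_under_ms": float(under.max()) if len(under) else 0.0,
            "max_over_ms": float(over.max()) if len(over) else 0.0,
            "sd_under_ms": float(under.std(ddof=1)) if len(under) > 1 else 0.0,
            "sd_over_ms": float(over.std(ddof=1)) if len(over) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def fit_subset_ls(data: pd.DataFrame, form: str,
                  free: Sequence[str], fixed_params: Mapping[str, float],
                  include: Sequence[str] = VARIABLES,
                  x0: Mapping[str, float] | None = None):
    """Least-squares fit over an arbitrary named subset of b1-b8.

    Diagnostic path used for oracle comparisons against brute-force grid
    search: all parameters not listed in ``free`` are clamped at
    ``fixed_params``.  Returns ``(params dict, rss)``.
    """
    free = list(free)
    y = data["P"].to_numpy(float)
    A, C = data["A"].to_numpy(float), data["C"].to_numpy(float)
    T, W = data["T"].to_numpy(float), data["W"].to_numpy(float)
    inc = _check_include(include)

    def rss_of(vals):
        p = dict(fixed_params)
        p.update(zip(free, vals))
        spec = ModelSpec(form, inc, p)
        r = y - predict_records(spec, A, C, T, W)
        return r

    start = np.array([(x0 or {}).get(n, fixed_params.get(n, 0.0)) for n in free])
    sol = optimize.least_squares(rss_of, start, method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    p = dict(fixed_params)
    p.update(zip(free, sol.x))
    return p, 2.0 * float(sol.cost)
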