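"""Nonlinear growth-curve families, pooled fitting, and AIC/BIC selection.

Five classical families are implemented, each parameterized by the mature
weight ``A`` (asymptote, grams), maturity rate ``K`` (per day) and a
time-scale parameter ``b``:

========== =============================
logistic        ``A / (1 + b e^{-Kt})``
gompertz        ``A exp(-b e^{-Kt})``
brody           ``A (1 - b e^{-Kt})``
von_bertalanffy ``A (1 - b e^{-Kt})^3``
richards        ``A (1 + s b e^{-Kt})^m``
========== =============================

Richards adds a free shape ``m`` and a fixed sign switch ``s`` (default -1,
under which Brody, Von Bertalanffy and, in the limit, Gompertz are special
cases; ``s=+1`` makes the logistic the ``m=-1`` member).  Model screening
fits population-level curves on all pooled records with a Gaussian
residual; the GWAS stage refits the chosen family under the full
mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import LongitudinalCohort

__all__ = [
    "FAMILIES",
    "GrowthFit",
    "GrowthCurveModel",
    "evaluate",
    "fit_growth",
    "fit_all_families",
    "select_model",
]


@dataclass(frozen=True)
class GrowthFamily:
    """A growth-curve mean function with analytic partial derivatives."""

    name: str
    param_names: tuple

    def mean(self, params: dict, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad(self, params: dict, t: np.ndarray) -> np.ndarray:
        """(len(t), n_params) Jacobian in ``param_names`` order."""
        raise NotImplementedError


def _expmKt(K, t):
    return np.exp(np.clip(-K * np.asarray(t, dtype=float), -700.0, 50.0))


class _Logistic(GrowthFamily):
    def mean(self, p, t):
        E = _expmKt(p["K"], t)
        return p["A"] / (1.0 + p["b"] * E)

    def grad(self, p, t):
        t = np.asarray(t, dtype=float)
        E = _expmKt(p["K"], t)
        D = 1.0 + p["b"] * E
        return np.stack(
            [1.0 / D, p["A"] * p["b"] * t * E / D**2, -p["A"] * E / D**2], axis=-1
        )


class _Gompertz(GrowthFamily):
    def mean(self, p, t):
        E = _expmKt(p["K"], t)
        return p["A"] * np.exp(-p["b"] * E)

    def grad(self, p, t):
        t = np.asarray(t, dtype=float)
        E = _expmKt(p["K"], t)
        core = np.exp(-p["b"] * E)
        return np.stack(
            [core, p["A"] * p["b"] * t * E * core, -p["A"] * E * core], axis=-1
        )


class _Brody(GrowthFamily):
    def mean(self, p, t):
        return p["A"] * (1.0 - p["b"] * _expmKt(p["K"], t))

    def grad(self, p, t):
        t = np.asarray(t, dtype=float)
        E = _expmKt(p["K"], t)
        return np.stack(
            [1.0 - p["b"] * E, p["A"] * p["b"] * t * E, -p["A"] * E], axis=-1
        )


class _VonBertalanffy(GrowthFamily):
    def mean(self, p, t):
        return p["A"] * (1.0 - p["b"] * _expmKt(p["K"], t)) ** 3

    def grad(self, p, t):
        t = np.asarray(t, dtype=float)
        E = _expmKt(p["K"], t)
        base = 1.0 - p["b"] * E
        return np.stack(
            [
                base**3,
                3.0 * p["A"] * p["b"] * t * E * base**2,
                -3.0 * p["A"] * E * base**2,
            ],
            axis=-1,
        )


class _Richards(GrowthFamily):
    """``A (1 + s b e^{-Kt})^m`` with fixed sign ``s``; base clipped positive."""

    sign: float = -1.0

    def _base(self, p, t):
        return np.maximum(1.0 + self.sign * p["b"] * _expmKt(p["K"], t), 1e-12)

    def mean(self, p, t):
        return p["A"] * self._base(p, t) ** p["m"]

    def grad(self, p, t):
        t = np.asarray(t, dtype=float)
        E = _expmKt(p["K"], t)
        base = self._base(p, t)
        powm1 = base ** (p["m"] - 1.0)
        return np.stack(
            [
                base ** p["m"],
                -p["A"] * p["m"] * self.sign * p["b"] * t * E * powm1,
                p["A"] * p["m"] * self.sign * E * powm1,
                p["A"] * base ** p["m"] * np.log(base),
            ],
            axis=-1,
        )


FAMILIES = {
    "logistic": _Logistic("logistic", ("A", "K", "b")),
    "gompertz": _Gompertz("gompertz", ("A", "K", "b")),
    "brody": _Brody("brody", ("A", "K", "b")),
    "von_bertalanffy": _VonBertalanffy("von_bertalanffy", ("A", "K", "b")),
    "richards": _Richards("richards", ("A", "K", "b", "m")),
}


def evaluate(family: str, params: dict, t) -> np.ndarray:
    """Evaluate a family's mean function at ages ``t`` (days)."""
    fam = FAMILIES[family]
    missing = set(fam.param_names) - set(params)
    if missing:
        raise ValueError(f"{family} needs parameters {sorted(missing)}")
    return fam.mean(params, np.asarray(t, dtype=float))


@dataclass
class GrowthFit:
    """One fitted growth curve with its Gaussian-ML information criteria."""

    family: str
    params: dict
    sigma2: float
    loglik: float
    n_params: int
    n_obs: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik


def _start_values(family: str, t: np.ndarray, w: np.ndarray, sign: float) -> dict:
    """Heuristic starts: A from 1.1*max(w); K, b from a log-linearization."""
    A0 = 1.1 * np.max(w)
    frac = np.clip(w / A0, 1e-6, 1.0 - 1e-6)
    if family == "logistic":
        z = np.log(1.0 / frac - 1.0)
    elif family == "gompertz":
        z = np.log(-np.log(frac))
    elif family == "brody":
        z = np.log(1.0 - frac)
    else:  # von_bertalanffy, richards: cube-root linearization
        z = np.log(1.0 - frac ** (1.0 / 3.0))
    slope, intercept = np.polyfit(t, z, 1)
    K0 = max(-slope, 1e-4)
    b0 = float(np.clip(np.exp(intercept), 1e-3, 1e3))
    start = {"A": A0, "K": K0, "b": b0}
    if family == "richards":
        start["m"] = 3.0
        if sign > 0:
            start["m"] = -1.0
            start["b"] = float(
                np.exp(np.polyfit(t, np.log(1.0 / frac - 1.0), 1)[1])
            )
    return start


class GrowthCurveModel(BaseEstimator, RegressorMixin):
    """Population-level nonlinear growth-curve regressor.

    Fits one family's mean curve to pooled (age, weight) records by least
    squares (equivalently Gaussian maximum likelihood), with analytic
    Jacobians.  Non-convergence is reported through ``converged_`` rather
    than raised.

    Parameters
    ----------
    family : str
        One of ``logistic``, ``gompertz``, ``brody``, ``von_bertalanffy``,
        ``richards``.
    sign : float, default -1.0
        Richards sign switch ``s``; ignored by the other families.
    start : dict, optional
        Starting parameter values; derived from the data when omitted.
    tol : float
        Termination tolerance passed to the optimizer.

    Attributes
    ----------
    params_ : dict            estimated parameters
    fit_ : GrowthFit          full fit record (loglik, AIC, BIC, ...)
    converged_ : bool
    """

    def __init__(self, family: str = "logistic", sign: float = -1.0, start: dict | None = None, tol: float = 1e-10):
        self.family = family
        self.sign = sign
        self.start = start
        self.tol = tol

    def fit(self, t, w=None):
        if isinstance(t, LongitudinalCohort):
            t, w = _pooled_records(t)
        t = np.asarray(t, dtype=float).ravel()
        w = np.asarray(w, dtype=float).ravel()
        ok = np.isfinite(t) & np.isfinite(w)
        t, w = t[ok], w[ok]
        fam = FAMILIES[self.family]
        if isinstance(fam, _Richards):
            fam = _Richards(fam.name, fam.param_names)
            object.__setattr__(fam, "sign", float(self.sign))
        k = len(fam.param_names)
        if len(np.unique(t)) < k:
            raise ValueError(
                f"{self.family} needs data at >= {k} distinct time points"
            )

        start = dict(self.start) if self.start else _start_values(self.family, t, w, self.sign)
        x0 = np.array([start[p] for p in fam.param_names], dtype=float)

        def resid(x):
            p = dict(zip(fam.param_names, x))
            return fam.mean(p, t) - w

        def jac(x):
            p = dict(zip(fam.param_names, x))
            return fam.grad(p, t)

        lower = np.full(k, -np.inf)
        upper = np.full(k, np.inf)
        lower[:3] = 1e-8  # A, K, b positive
        converged = True
        try:
            res = least_squares(
                resid, x0, jac=jac, bounds=(lower, upper),
                xtol=self.tol, ftol=self.tol, gtol=self.tol, max_nfev=2000,
            )
            x = res.x
            converged = bool(res.success) and np.all(np.isfinite(x))
            # treat runaway shape parameters / boundary solutions as failures
            if self.family == "richards" and (abs(x[-1]) > 50 or x[2] <= 2e-8):
                converged = False
        except Exception:
            x = x0
            converged = False

        params = dict(zip(fam.param_names, (float(v) for v in x)))
        rss = float(np.sum(resid(x) ** 2))
        n = len(w)
        sigma2 = rss / n
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) if sigma2 > 0 else np.inf
        self.params_ = params
        self.converged_ = converged
        self.fit_ = GrowthFit(
            family=self.family,
            params=params,
            sigma2=sigma2,
            loglik=float(loglik),
            n_params=k + 1,  # curve parameters + residual variance
            n_obs=n,
            converged=converged,
        )
        self.aic_ = self.fit_.aic
        self.bic_ = self.fit_.bic
        return self

    def predict(self, t):
        return evaluate(self.family, self.params_, t)


def _pooled_records(cohort: LongitudinalCohort):
    W = cohort.weight_matrix
    tt = np.broadcast_to(cohort.schedule.astype(float), W.shape)
    ok = np.isfinite(W)
    return tt[ok], W[ok]


def fit_growth(
    cohort, family: str = "logistic", start: dict | None = None, tol: float = 1e-10,
    sign: float = -1.0,
) -> GrowthFit:
    """Fit one family to a cohort's pooled records; returns a :class:`GrowthFit`."""
    return GrowthCurveModel(family=family, sign=sign, start=start, tol=tol).fit(cohort).fit_


def fit_all_families(cohort, families=None) -> dict:
    """Fit every requested family (default: all five) to the pooled records."""
    families = families or list(FAMILIES)
    return {name: fit_growth(cohort, family=name) for name in families}


def select_model(fits) -> GrowthFit:
    """Pick the converged fit with the lowest AIC.

    Ties are broken by the lower BIC, then by fewer parameters.  Raises if no
    fit converged.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged growth-curve fit to select from")
    return min(converged, key=lambda f: (f.aic, f.bic, f.n_params))
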