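"""Single-step nonlinear mixed models for logistic growth trajectories.

The observation model for individual ``i`` at age ``t`` is

.. math::

    w_{it} = \\frac{\\mu_A + \\mathrm{Sex} + \\mathrm{PC} [+ \\mathrm{SNP}] + \\varepsilon_{Ai}}
                  {1 + \\mu_b \\exp[-(\\mu_K + \\mathrm{Sex} + \\mathrm{PC}
                  [+ \\mathrm{SNP}] + \\varepsilon_{Ki}) t]} + e_{it},

with individual deviations ``(eps_A, eps_K) ~ N(0, Sigma)`` (2x2, possibly
singular), i.i.d. residuals ``e ~ N(0, sigma2_e)``, and a shared time-scale
``mu_b`` carrying no covariates or random effect.  Four model variants differ
only in where the additive SNP dosage enters: nowhere (M0, the null), both
linear predictors (M1), the mature-weight part only (M2), or the
maturity-rate part only (M3).

The marginal likelihood integrates the bivariate random effect out of the
nonlinear mean.  The working approximation is the first-order conditional
(Lindstrom-Bates / FOCE) expansion: per individual, the penalized
conditional mode of the random effect is located by damped Gauss-Newton and
the mean is linearized there, giving a closed-form Gaussian marginal term.
An adaptive Gauss-Hermite quadrature implementation of the same integral is
provided as an independent numerical oracle for tests.

Everything is fitted by maximum likelihood (never REML) so that
likelihood-ratio tests between models differing in fixed effects are valid;
the LRT statistic is referred to a chi-square whose degrees of freedom equal
the parameter-count difference of the nested models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .containers import LongitudinalCohort
from .growth import GrowthCurveModel

__all__ = [
    "SNP_TARGETS",
    "NMMParams",
    "NMMFit",
    "LRTResult",
    "NonlinearMixedModel",
    "fit_nmm",
    "marginal_loglik",
    "quadrature_loglik",
    "lrt",
]

#: model label -> which linear predictors receive the SNP dosage
SNP_TARGETS = {
    "none": (),          # M0
    "both": ("A", "K"),  # M1
    "A": ("A",),         # M2
    "K": ("K",),         # M3
}

_PENALTY = 1e10


# ---------------------------------------------------------------------------
# parameter and result containers
# ---------------------------------------------------------------------------


@dataclass
class NMMParams:
    """NMM parameters on the original scale (grams / per-day).

    ``beta_A``/``beta_K`` follow the design-column order
    ``intercept, <covariates...>[, snp]``; ``Sigma`` is the 2x2 random-effect
    covariance (rows/cols: A then K) and may be singular or zero.
    """

    beta_A: np.ndarray
    beta_K: np.ndarray
    b: float
    Sigma: np.ndarray
    sigma2_e: float

    def __post_init__(self):
        self.beta_A = np.atleast_1d(np.asarray(self.beta_A, dtype=float))
        self.beta_K = np.atleast_1d(np.asarray(self.beta_K, dtype=float))
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (2, 2):
            raise ValueError("Sigma must be 2x2")
        if abs(self.Sigma[0, 1] - self.Sigma[1, 0]) > 1e-10 * (1 + abs(self.Sigma).max()):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma)[0] < -1e-10 * max(1.0, self.Sigma.trace()):
            raise ValueError("Sigma must be positive semi-definite")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if self.b <= 0:
            raise ValueError("b must be positive")


@dataclass
class NMMFit:
    """A fitted nonlinear mixed model."""

    params: NMMParams
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    snp_target: str
    design_columns: tuple
    random_effects: pd.DataFrame | None = None  # conditional modes (eps_A, eps_K)

    @property
    def mu_A(self) -> float:
        return float(self.params.beta_A[0])

    @property
    def mu_K(self) -> float:
        return float(self.params.beta_K[0])

    @property
    def mu_b(self) -> float:
        return float(self.params.b)


@dataclass
class LRTResult:
    """Likelihood-ratio test of a SNP model against the null."""

    statistic: float
    df: int
    p_value: float
    available: bool = True


# ---------------------------------------------------------------------------
# design construction and scaling
# ---------------------------------------------------------------------------


def build_design(
    cohort: LongitudinalCohort,
    snp_target: str = "none",
    dosage: np.ndarray | None = None,
    covariates: list | None = None,
):
    """Design matrices for the A- and K-part linear predictors.

    Columns are an intercept followed by mean-centered covariates (sex plus
    any cohort covariate columns, e.g. PC1..PC5) and, in models that carry
    it, the mean-centered SNP dosage as the last column.  Centering makes the
    intercepts the population means ``mu_A`` and ``mu_K``.
    """
    if snp_target not in SNP_TARGETS:
        raise ValueError(f"snp_target must be one of {sorted(SNP_TARGETS)}")
    n = cohort.n_individuals
    if covariates is None:
        covariates = ["sex"] + list(cohort.covariate_columns)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in covariates:
        v = cohort.individuals[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c)
    X = np.column_stack(cols)
    targets = SNP_TARGETS[snp_target]
    if targets:
        if dosage is None:
            raise ValueError(f"snp_target={snp_target!r} requires a dosage vector")
        d = np.asarray(dosage, dtype=float)
        if d.shape != (n,) or np.isnan(d).any():
            raise ValueError("dosage must be complete and one value per individual")
        snp_col = (d - d.mean())[:, None]
    X_A = np.hstack([X, snp_col]) if "A" in targets else X
    X_K = np.hstack([X, snp_col]) if "K" in targets else X
    names_A = tuple(names + (["snp"] if "A" in targets else []))
    names_K = tuple(names + (["snp"] if "K" in targets else []))
    return X_A, X_K, names_A, names_K


class _NMMData:
    """Scaled working arrays shared by the likelihood code.

    Weights are divided by the overall mean weight and ages by the mean
    scheduled age so that every free parameter is O(1) for the optimizer;
    log-likelihoods are mapped back to the gram scale on output.
    """

    def __init__(self, cohort, snp_target="none", dosage=None, covariates=None):
        W = cohort.weight_matrix
        self.mask = np.isfinite(W)
        if self.mask.sum() == 0:
            raise ValueError("cohort has no observed records")
        n_per_ind = self.mask.sum(axis=1)
        if (n_per_ind == 0).any():
            raise ValueError("every individual needs at least one record")
        t = cohort.schedule.astype(float)
        if len(t) < 2 or np.nanstd(W) == 0:
            raise ValueError("degenerate data: need >=2 time points with variation")
        self.y_scale = float(np.nanmean(W))
        self.t_scale = float(np.mean(t))
        self.y = np.where(self.mask, W / self.y_scale, 0.0)
        self.t = t / self.t_scale
        self.n_obs_i = n_per_ind.astype(float)
        self.n_obs = float(self.mask.sum())
        self.X_A, self.X_K, self.names_A, self.names_K = build_design(
            cohort, snp_target, dosage, covariates
        )
        self.p_A = self.X_A.shape[1]
        self.p_K = self.X_K.shape[1]
        self.n_params = self.p_A + self.p_K + 1 + 3 + 1  # + mu_b + Sigma + sigma2_e
        self.n_theta = self.p_A + self.p_K + 5
        self.ids = cohort.ids

    # -- packing ----------------------------------------------------------

    def pack(self, params: NMMParams) -> np.ndarray:
        """Original-scale parameters -> scaled optimizer vector."""
        D = np.diag([1.0 / self.y_scale, self.t_scale])
        S = D @ params.Sigma @ D
        vals, vecs = np.linalg.eigh(S)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        q, r = np.linalg.qr(root.T)
        L = r.T
        sign = np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))
        L = L * sign
        if params.beta_A.size != self.p_A or params.beta_K.size != self.p_K:
            raise ValueError("coefficient vectors do not match the design")
        return np.concatenate(
            [
                params.beta_A / self.y_scale,
                params.beta_K * self.t_scale,
                [np.log(params.b)],
                [L[0, 0], L[1, 0], L[1, 1]],
                [0.5 * np.log(params.sigma2_e) - np.log(self.y_scale)],
            ]
        )

    def unpack(self, theta: np.ndarray) -> NMMParams:
        """Scaled optimizer vector -> original-scale parameters."""
        pA, pK = self.p_A, self.p_K
        beta_A = theta[:pA] * self.y_scale
        beta_K = theta[pA : pA + pK] / self.t_scale
        b = float(np.exp(theta[pA + pK]))
        l11, l21, l22 = theta[pA + pK + 1 : pA + pK + 4]
        L = np.array([[l11, 0.0], [l21, l22]])
        Dinv = np.diag([self.y_scale, 1.0 / self.t_scale])
        Sigma = Dinv @ (L @ L.T) @ Dinv
        Sigma = 0.5 * (Sigma + Sigma.T)
        sigma2_e = float(np.exp(2.0 * theta[-1]) * self.y_scale**2)
        return NMMParams(beta_A, beta_K, b, Sigma, sigma2_e)


# ---------------------------------------------------------------------------
# FOCE marginal log-likelihood (batched over parameter vectors)
# ---------------------------------------------------------------------------


def _foce_nll(data: _NMMData, thetas: np.ndarray, u0: np.ndarray | None = None,
              max_inner: int = 60, inner_tol: float = 1e-9, return_u: bool = False):
    """Negative FOCE marginal log-likelihood for a batch of parameter vectors.

    ``thetas`` has shape (B, P); returns (B,) values on the *original* gram
    scale.  ``u0`` (n, 2) warm-starts the whitened conditional modes.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    B, _ = thetas.shape
    mask = data.mask
    n, T = mask.shape
    y, t = data.y, data.t
    pA, pK = data.p_A, data.p_K

    alpha_A = thetas[:, :pA] @ data.X_A.T                     # (B, n)
    alpha_K = thetas[:, pA : pA + pK] @ data.X_K.T            # (B, n)
    b = np.exp(thetas[:, pA + pK])[:, None, None]             # (B, 1, 1)
    l11 = thetas[:, pA + pK + 1][:, None]                     # (B, 1)
    l21 = thetas[:, pA + pK + 2][:, None]
    l22 = thetas[:, pA + pK + 3][:, None]
    sig2 = np.exp(2.0 * thetas[:, -1])[:, None]               # (B, 1)

    if u0 is None:
        u = np.zeros((B, n, 2))
    else:
        u = np.broadcast_to(u0, (B, n, 2)).copy()

    maskf = mask.astype(float)

    def residual_jac(u):
        A = alpha_A + l11 * u[..., 0]                         # (B, n)
        K = alpha_K + l21 * u[..., 0] + l22 * u[..., 1]
        Z = np.exp(np.clip(K[..., None] * (-t), -700.0, 50.0))  # (B, n, T)
        D = 1.0 + b * Z
        Dinv = maskf / D
        m = A[..., None] * Dinv
        r = y * maskf - m
        # J columns: derivatives of the mean w.r.t. the whitened effects u1, u2
        dK = A[..., None] * (b * t) * Z * Dinv * Dinv  # mask^2 == mask
        J1 = Dinv * l11[..., None] + dK * l21[..., None]
        J2 = dK * l22[..., None]
        return r, J1, J2

    # Gauss-Newton for the penalized conditional modes.  The map is strongly
    # contractive for realistic variance ratios; a per-member trust clip on
    # the step guards the extreme parameter values visited by line searches.
    r, J1, J2 = residual_jac(u)
    for _ in range(max_inner):
        g1 = (J1 * r).sum(axis=-1) / sig2 - u[..., 0]         # -(df/du)
        g2 = (J2 * r).sum(axis=-1) / sig2 - u[..., 1]
        G11 = (J1 * J1).sum(axis=-1) / sig2 + 1.0
        G12 = (J1 * J2).sum(axis=-1) / sig2
        G22 = (J2 * J2).sum(axis=-1) / sig2 + 1.0
        det = G11 * G22 - G12**2
        d1 = (G22 * g1 - G12 * g2) / det
        d2 = (G11 * g2 - G12 * g1) / det
        norm = np.sqrt(d1**2 + d2**2)
        clip = np.minimum(1.0, 4.0 / np.maximum(norm, 1e-300))
        u = u + np.stack([d1 * clip, d2 * clip], axis=-1)
        r, J1, J2 = residual_jac(u)
        if np.nanmax(norm) < inner_tol:
            break

    # FOCE Gaussian marginal about the linearization at the mode
    G11 = (J1 * J1).sum(axis=-1)
    G12 = (J1 * J2).sum(axis=-1)
    G22 = (J2 * J2).sum(axis=-1)
    detC = (sig2 + G11) * (sig2 + G22) - G12**2
    rt = r + J1 * u[..., 0:1] + J2 * u[..., 1:2]
    h1 = (J1 * rt).sum(axis=-1)
    h2 = (J2 * rt).sum(axis=-1)
    ss = (rt**2).sum(axis=-1)
    quad = (ss - (h1**2 * (sig2 + G22) - 2.0 * h1 * h2 * G12 + h2**2 * (sig2 + G11)) / detC) / sig2
    logdetV = (data.n_obs_i - 2.0) * np.log(sig2) + np.log(detC)
    ll_i = -0.5 * (data.n_obs_i * np.log(2.0 * np.pi) + logdetV + quad)
    nll = -(ll_i.sum(axis=-1) - data.n_obs * np.log(data.y_scale))
    nll = np.where(np.isfinite(nll), nll, _PENALTY)
    if return_u:
        return nll, u
    return nll


def _fd_value_and_grad(data, theta, u_cache, h_rel=1e-4):
    """Objective and central-difference gradient in one batched call."""
    P = theta.size
    h = h_rel * np.maximum(1.0, np.abs(theta))
    batch = np.concatenate(
        [theta[None, :], theta[None, :] + np.diag(h), theta[None, :] - np.diag(h)]
    )
    vals, u_all = _foce_nll(data, batch, u0=u_cache["u"], return_u=True)
    u_cache["u"] = u_all[0]
    grad = (vals[1 : P + 1] - vals[P + 1 :]) / (2.0 * h)
    return vals[0], grad


# ---------------------------------------------------------------------------
# public likelihood functions
# ---------------------------------------------------------------------------


def marginal_loglik(
    params: NMMParams,
    cohort: LongitudinalCohort,
    dosage: np.ndarray | None = None,
    snp_target: str = "none",
    covariates: list | None = None,
) -> float:
    """FOCE approximate marginal log-likelihood at the given parameters.

    With ``Sigma = 0`` this reduces exactly to the i.i.d. Gaussian nonlinear
    regression log-likelihood.
    """
    data = _NMMData(cohort, snp_target, dosage, covariates)
    theta = data.pack(params)
    return float(-_foce_nll(data, theta[None, :])[0])


def quadrature_loglik(
    params: NMMParams,
    cohort: LongitudinalCohort,
    dosage: np.ndarray | None = None,
    snp_target: str = "none",
    covariates: list | None = None,
    n_nodes: int = 21,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (test oracle).

    Each individual's conditional likelihood is numerically integrated over
    the random effects on a whitened scale, with the grid centered at the
    conditional mode and scaled by the Gauss-Newton curvature there.
    Singular ``Sigma`` directions are handled by integrating only over the
    non-degenerate eigen-directions (a zero ``Sigma`` degenerates to the
    plain Gaussian log-likelihood).  Used only in tests; per-individual
    Python loops.
    """
    if n_nodes < 5:
        raise ValueError("need at least 5 quadrature nodes")
    data = _NMMData(cohort, snp_target, dosage, covariates)
    ys, ts = data.y_scale, data.t_scale
    # scaled quantities
    beta_A = params.beta_A / ys
    beta_K = params.beta_K * ts
    D = np.diag([1.0 / ys, ts])
    S = D @ params.Sigma @ D
    b = params.b
    sig2 = params.sigma2_e / ys**2
    alpha_A = data.X_A @ beta_A
    alpha_K = data.X_K @ beta_K

    vals, vecs = np.linalg.eigh(S)
    keep = vals > 1e-12 * max(1.0, vals.max())
    R = vecs[:, keep] * np.sqrt(vals[keep])  # eps = R @ v, v ~ N(0, I_r)
    r_dim = R.shape[1]

    nodes, weights = hermegauss(n_nodes)  # weight e^{-z^2/2}, sum w = sqrt(2 pi)

    def cond_resid_jac(i, v):
        eps = R @ v if r_dim else np.zeros(2)
        A = alpha_A[i] + eps[0]
        K = alpha_K[i] + eps[1]
        tt = data.t[data.mask[i]]
        Z = np.exp(np.clip(-K * tt, -700.0, 50.0))
        Dd = 1.0 + b * Z
        m = A / Dd
        r = data.y[i, data.mask[i]] - m
        dA = 1.0 / Dd
        dK = A * b * tt * Z / Dd**2
        J = np.column_stack([dA, dK]) @ R if r_dim else np.zeros((tt.size, 0))
        return r, J

    total = 0.0
    log_norm = -0.5 * np.log(2.0 * np.pi * sig2)
    for i in range(data.mask.shape[0]):
        n_i = int(data.n_obs_i[i])
        if r_dim == 0:
            r, _ = cond_resid_jac(i, np.zeros(0))
            total += n_i * log_norm - 0.5 * (r**2).sum() / sig2
            continue
        # conditional mode by damped Gauss-Newton on v
        v = np.zeros(r_dim)
        r, J = cond_resid_jac(i, v)
        f = 0.5 * (r**2).sum() / sig2 + 0.5 * v @ v
        for _ in range(200):
            H = J.T @ J / sig2 + np.eye(r_dim)
            g = J.T @ r / sig2 - v
            step = np.linalg.solve(H, g)
            scale = 1.0
            for _ in range(30):
                v_new = v + scale * step
                r_new, J_new = cond_resid_jac(i, v_new)
                f_new = 0.5 * (r_new**2).sum() / sig2 + 0.5 * v_new @ v_new
                if f_new <= f + 1e-14:
                    break
                scale *= 0.5
            if f_new > f + 1e-14:
                break
            v, r, J, f = v_new, r_new, J_new, f_new
            if np.abs(scale * step).max() < 1e-12:
                break
        H = J.T @ J / sig2 + np.eye(r_dim)
        Lam = np.linalg.cholesky(np.linalg.inv(H))
        # tensor-product adaptive grid: v = v_hat + Lam z, z_j ~ hermegauss
        grids = np.meshgrid(*([nodes] * r_dim), indexing="ij")
        wgrids = np.meshgrid(*([weights] * r_dim), indexing="ij")
        Zs = np.stack([g.ravel() for g in grids], axis=-1)      # (M, r)
        Ws = np.prod(np.stack([g.ravel() for g in wgrids], axis=-1), axis=-1)
        logvals = np.empty(Zs.shape[0])
        for k, z in enumerate(Zs):
            vk = v + Lam @ z
            rk, _ = cond_resid_jac(i, vk)
            log_joint = (
                n_i * log_norm
                - 0.5 * (rk**2).sum() / sig2
                - 0.5 * r_dim * np.log(2.0 * np.pi)
                - 0.5 * vk @ vk
            )
            logvals[k] = log_joint + 0.5 * z @ z + np.log(Ws[k])
        _, logdet = np.linalg.slogdet(Lam)
        m = logvals.max()
        total += logdet + m + np.log(np.exp(logvals - m).sum())
    return float(total - data.n_obs * np.log(ys))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class NonlinearMixedModel(BaseEstimator):
    """Maximum-likelihood single-step NMM estimator (sklearn-style).

    Parameters
    ----------
    snp_target : {"none", "both", "A", "K"}
        Where the SNP dosage enters: M0, M1, M2 or M3 respectively.
    covariates : list of str, optional
        Individual-level fixed-effect columns; defaults to ``sex`` plus every
        covariate column on the cohort (e.g. attached PCA scores).
    start : NMMParams or NMMFit, optional
        Warm start (typically the fitted null model when scanning SNPs).
    max_iter, tol, gtol : optimizer controls
        Convergence: relative log-likelihood change below ``tol`` or
        projected gradient below ``gtol``; iteration cap reported through
        ``converged_`` rather than raised.

    Attributes
    ----------
    params_ : NMMParams
    loglik_ : float
    n_params_ : int
    converged_ : bool
    fit_ : NMMFit
    mu_A_, mu_K_, mu_b_ : floats (population means)
    random_effects_ : DataFrame of conditional modes (eps_A, eps_K)
    """

    def __init__(
        self,
        snp_target: str = "none",
        covariates: list | None = None,
        start=None,
        max_iter: int = 200,
        tol: float = 1e-8,
        gtol: float = 1e-5,
    ):
        self.snp_target = snp_target
        self.covariates = covariates
        self.start = start
        self.max_iter = max_iter
        self.tol = tol
        self.gtol = gtol

    # -- starting values ---------------------------------------------------

    def _theta0(self, data: _NMMData, cohort) -> np.ndarray:
        start = self.start
        if isinstance(start, NMMFit):
            start = start.params
        if isinstance(start, NMMParams):
            beta_A = np.zeros(data.p_A)
            beta_K = np.zeros(data.p_K)
            beta_A[: start.beta_A.size] = start.beta_A
            beta_K[: start.beta_K.size] = start.beta_K
            padded = NMMParams(beta_A, beta_K, start.b, start.Sigma, start.sigma2_e)
            return data.pack(padded)
        pooled = GrowthCurveModel(family="logistic").fit(cohort)
        A0, K0, b0 = (pooled.params_[k] for k in ("A", "K", "b"))
        s2 = max(pooled.fit_.sigma2, 1e-8)
        beta_A = np.zeros(data.p_A)
        beta_K = np.zeros(data.p_K)
        beta_A[0] = A0
        beta_K[0] = K0
        Sigma0 = np.diag([(0.08 * A0) ** 2, (0.10 * K0) ** 2])
        return data.pack(NMMParams(beta_A, beta_K, b0, Sigma0, 0.5 * s2))

    # -- fitting -----------------------------------------------------------

    def fit(self, cohort: LongitudinalCohort, dosage: np.ndarray | None = None):
        data = _NMMData(cohort, self.snp_target, dosage, self.covariates)
        theta0 = self._theta0(data, cohort)
        u_cache = {"u": np.zeros((data.mask.shape[0], 2))}

        def fun(theta):
            return _fd_value_and_grad(data, theta, u_cache)

        res = optimize.minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": self.max_iter,
                "ftol": self.tol * 1e-2,
                "gtol": self.gtol,
                "maxcor": 20,
            },
        )
        theta = res.x
        nll, u_hat = _foce_nll(data, theta[None, :], u0=u_cache["u"], return_u=True)
        params = data.unpack(theta)
        converged = bool(res.success or res.status == 0) and np.isfinite(nll[0])
        if res.status == 1:  # iteration cap
            converged = False

        L = np.array(
            [
                [theta[data.p_A + data.p_K + 1], 0.0],
                [theta[data.p_A + data.p_K + 2], theta[data.p_A + data.p_K + 3]],
            ]
        )
        eps = u_hat[0] @ L.T
        Dinv = np.array([data.y_scale, 1.0 / data.t_scale])
        re = pd.DataFrame(
            eps * Dinv, index=pd.Index(data.ids, name="individual_id"),
            columns=["eps_A", "eps_K"],
        )

        self.params_ = params
        self.loglik_ = float(-nll[0])
        self.n_params_ = data.n_params
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        self.random_effects_ = re
        self.mu_A_ = float(params.beta_A[0])
        self.mu_K_ = float(params.beta_K[0])
        self.mu_b_ = float(params.b)
        self.beta_A_ = pd.Series(params.beta_A, index=list(data.names_A))
        self.beta_K_ = pd.Series(params.beta_K, index=list(data.names_K))
        self.fit_ = NMMFit(
            params=params,
            loglik=self.loglik_,
            n_params=self.n_params_,
            converged=converged,
            n_iter=self.n_iter_,
            snp_target=self.snp_target,
            design_columns=(data.names_A, data.names_K),
            random_effects=re,
        )
        self._data = data
        self._theta = theta
        return self

    # -- post-fit utilities -------------------------------------------------

    def loglik_at(self, params: NMMParams) -> float:
        """Objective re-evaluated at arbitrary parameters (same design)."""
        return float(-_foce_nll(self._data, self._data.pack(params)[None, :])[0])

    def standard_errors(self, h_rel: float = 1e-4) -> dict:
        """Asymptotic SEs from a finite-difference observed information matrix.

        Returns a dict with entries ``beta_A`` and ``beta_K`` (pandas Series,
        original scale).  The information matrix is inverted on the scaled
        parameterization; non-positive curvature yields NaN entries.
        """
        data, theta = self._data, self._theta
        P = theta.size
        h = h_rel * np.maximum(1.0, np.abs(theta))
        grads = np.empty((P, P))
        u0 = np.zeros((data.mask.shape[0], 2))
        cache = {"u": u0}
        for j in range(P):
            tp = theta.copy()
            tp[j] += h[j]
            _, gp = _fd_value_and_grad(data, tp, cache)
            tm = theta.copy()
            tm[j] -= h[j]
            _, gm = _fd_value_and_grad(data, tm, cache)
            grads[j] = (gp - gm) / (2.0 * h[j])
        H = 0.5 * (grads + grads.T)
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                se = np.full(P, np.nan)
        se_A = se[: data.p_A] * data.y_scale
        se_K = se[data.p_A : data.p_A + data.p_K] / data.t_scale
        return {
            "beta_A": pd.Series(se_A, index=list(data.names_A)),
            "beta_K": pd.Series(se_K, index=list(data.names_K)),
        }


def fit_nmm(
    cohort: LongitudinalCohort,
    dosage: np.ndarray | None = None,
    snp_target: str = "none",
    covariates: list | None = None,
    start=None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> NMMFit:
    """Fit one of the four NMMs by maximum likelihood; returns :class:`NMMFit`."""
    est = NonlinearMixedModel(
        snp_target=snp_target,
        covariates=covariates,
        start=start,
        max_iter=max_iter,
        tol=tol,
    ).fit(cohort, dosage)
    return est.fit_


def lrt(fit_alt: NMMFit, fit_null: NMMFit) -> LRTResult:
    """Likelihood-ratio test of a nested pair of NMM fits.

    The statistic ``2 (logLik_alt - logLik_null)`` is clamped at zero; the
    degrees of freedom are the parameter-count difference.  If either fit
    failed to converge the result is marked unavailable (NaN p).
    """
    df = fit_alt.n_params - fit_null.n_params
    if df < 1:
        raise ValueError("alternative must have more parameters than the null")
    if not (fit_alt.converged and fit_null.converged):
        return LRTResult(statistic=np.nan, df=df, p_value=np.nan, available=False)
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))
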