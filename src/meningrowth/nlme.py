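"""Nonlinear multilevel mixed-effects fitting of tumor growth laws.

Each growth law is fitted as a two-level model: scans nested in patients,
with patient-level Gaussian random effects b_i ~ N(0, Psi) perturbing a
subset of the mean-function parameters and i.i.d. Gaussian residuals of
variance sigma^2 on the model's response scale,

    y_ij = mu(t_ij; theta + A b_i) + eps_ij .

The marginal likelihood integrates the random effects out patient by
patient. The working approximation is the Laplace method: the integrand is
expanded to second order at its mode, with the Gauss-Newton curvature
J'J/sigma^2 + Psi^{-1} (J the Jacobian of the mean in b). For any model
whose mean is linear in its random effects — the linear and exponential
laws always, and the Gompertz law with random effects on (log V0, log K) —
the integrand is exactly Gaussian and the Laplace value is exact. Adaptive
Gauss-Hermite quadrature over the same integral is provided as a
high-accuracy cross-check for the genuinely nonlinear cases.

Maximization is multi-start quasi-Newton over (theta, Psi, sigma^2), with
Psi kept positive definite through a log-Cholesky parameterization and
positive natural parameters optimized on the log scale. Standard errors
come from the inverse observed information (numerical Hessian of the
negative marginal log-likelihood over all parameters jointly, fixed-effect
block). Models are compared by maximized log-likelihood, AIC and BIC; note
the linear law is scored on the volume scale and the others on the log
scale, so the default comparison mixes scales exactly as a
goodness-of-fit-per-model table does — a Jacobian-corrected column putting
everything on the volume scale is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort
from .models import (
    GrowthModel,
    GrowthModelDomainError,
    get_model,
    mean_gradient,
    mean_response,
)

__all__ = [
    "RandomEffectSpec",
    "FitConfig",
    "FitResult",
    "CovariateDesign",
    "default_re_spec",
    "marginal_loglik_laplace",
    "marginal_loglik_quadrature",
    "fit_nlme",
    "information_criteria",
    "compare_models",
]

_BIG = 1e10


@dataclass(frozen=True)
class RandomEffectSpec:
    """Which mean parameters carry patient-level random effects."""

    random_params: tuple[str, ...]
    covariance: str = "unstructured"  # or "diagonal"

    def __post_init__(self):
        if len(self.random_params) == 0:
            raise ValueError("need at least one random parameter")
        if self.covariance not in ("unstructured", "diagonal"):
            raise ValueError("covariance must be 'unstructured' or 'diagonal'")

    @property
    def q(self) -> int:
        return len(self.random_params)

    @property
    def n_cov_params(self) -> int:
        q = self.q
        return q * (q + 1) // 2 if self.covariance == "unstructured" else q


def default_re_spec(model_name: str) -> RandomEffectSpec:
    """Default random-effect structure per growth law.

    Gompertz: (log V0, log K) unstructured — baseline and attained size are
    the dominant sources of between-patient heterogeneity. Two-parameter
    laws: both parameters (intercept-like and rate), unstructured.
    """
    return RandomEffectSpec(
        {
            "gompertz": ("log_v0", "log_k"),
            "exponential": ("log_v0", "alpha"),
            "radial": ("r0", "alpha"),
            "linear": ("intercept", "slope"),
        }[model_name]
    )


@dataclass(frozen=True)
class CovariateDesign:
    """Per-patient covariates entering linearly on one fixed-effect parameter."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (n_patients, n_covariates)
    placement: str  # mean-function parameter the covariates shift

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("covariate matrix shape does not match names")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_nlme`."""

    n_starts: int = 5
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-10
    perturb_scale: float = 0.3
    compute_se: bool = True
    inner_tol: float = 1e-11  # Newton-decrement threshold at the inner mode
    inner_maxiter: int = 50


@dataclass(frozen=True)
class FitResult:
    """A fitted mixed-effects growth model."""

    model: str
    theta_hat: dict
    se_theta: dict
    psi_hat: np.ndarray
    re_params: tuple
    sigma2_hat: float
    loglik: float
    k: int
    n_obs: int
    n_patients: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    response_scale: str
    covariate_names: tuple = ()
    vcov: np.ndarray = field(default=None, repr=False, compare=False)
    param_order: tuple = ()

    def __post_init__(self):
        assert abs(self.aic - (2 * self.k - 2 * self.loglik)) < 1e-8
        assert abs(self.bic - (self.k * math.log(self.n_obs) - 2 * self.loglik)) < 1e-8
        assert self.sigma2_hat > 0
        assert np.allclose(self.psi_hat, self.psi_hat.T)


# ---------------------------------------------------------------------------
# data preparation


def _prepare(model: GrowthModel, cohort: Cohort):
    """Per-patient (t, y) arrays on the model's response scale."""
    data = []
    for patient in cohort:
        t = patient.times
        v = patient.volumes
        y = np.log(v) if model.response_scale == "log_volume" else v
        data.append((t, y))
    return data


def _is_linear_in_b(model: GrowthModel, random_params: tuple[str, ...]) -> bool:
    if model.name in ("linear", "exponential"):
        return True
    if model.name == "gompertz":
        return set(random_params) <= {"log_k", "log_v0"}
    return False


# ---------------------------------------------------------------------------
# per-patient Laplace machinery


def _penalized_sse(model, t, y, phi_base, re_idx, b, psi_inv, sigma2):
    phi = phi_base.copy()
    phi[re_idx] += b
    mu = mean_response(model, phi, t)
    r = y - mu
    return float(r @ r) / sigma2 + float(b @ psi_inv @ b), phi, r


def _small_solve(H, g):
    """Solve H x = g for the tiny (q <= 2) symmetric systems of the inner step."""
    if g.size == 1:
        return g / H[0, 0]
    if g.size == 2:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
            x = np.array(
                [
                    (H[1, 1] * g[0] - H[0, 1] * g[1]) / det,
                    (H[0, 0] * g[1] - H[1, 0] * g[0]) / det,
                ]
            )
        if np.all(np.isfinite(x)):
            return x
    return np.linalg.solve(H, g)


def _inner_mode(model, t, y, phi_base, re_idx, psi_inv, sigma2, linear_in_b,
                tol=1e-11, maxiter=50, b0=None):
    """Mode of the per-patient joint log-density over b (Gauss-Newton steps).

    Returns (b_hat, H, r, phi) with H the Gauss-Newton curvature at the
    mode. Exact in one step when the mean is linear in b. ``b0`` warm-starts
    the search (falling back to 0 if it is outside the mean's domain).
    """
    q = len(re_idx)
    b = np.zeros(q)
    if b0 is not None:
        try:
            _penalized_sse(model, t, y, phi_base, re_idx, b0, psi_inv, sigma2)
            b = np.asarray(b0, dtype=float)
        except GrowthModelDomainError:
            pass
    obj, phi, r = _penalized_sse(model, t, y, phi_base, re_idx, b, psi_inv, sigma2)
    n_iter = maxiter if not linear_in_b else 2
    for _ in range(n_iter):
        J = mean_gradient(model, phi, t)[:, re_idx]
        H = J.T @ J / sigma2 + psi_inv
        grad = J.T @ r / sigma2 - psi_inv @ b
        delta = _small_solve(H, grad)
        # the Laplace log-likelihood error at an approximate mode is about
        # half the Newton decrement, so stop on the decrement itself
        if float(grad @ delta) < tol:
            break
        step = 1.0
        for _ in range(30):
            b_new = b + step * delta
            try:
                obj_new, phi_new, r_new = _penalized_sse(
                    model, t, y, phi_base, re_idx, b_new, psi_inv, sigma2
                )
            except GrowthModelDomainError:
                step *= 0.5
                continue
            if obj_new <= obj + 1e-12:
                b, obj, phi, r = b_new, obj_new, phi_new, r_new
                break
            step *= 0.5
        else:
            break  # no improving step; accept current point
    J = mean_gradient(model, phi, t)[:, re_idx]
    H = J.T @ J / sigma2 + psi_inv
    return b, H, r, phi


def _patient_laplace(model, t, y, phi_base, re_idx, psi_inv, logdet_psi, sigma2,
                     linear_in_b, tol, maxiter):
    if linear_in_b:
        # mean is exactly mu0 + J b: the mode is one solve and Laplace is exact
        mu = mean_response(model, phi_base, t)
        r0 = y - mu
        J = mean_gradient(model, phi_base, t)[:, re_idx]
        H = J.T @ J / sigma2 + psi_inv
        b = np.linalg.solve(H, J.T @ r0 / sigma2)
        r = r0 - J @ b
    else:
        b, H, r, _ = _inner_mode(
            model, t, y, phi_base, re_idx, psi_inv, sigma2, linear_in_b, tol, maxiter
        )
    n_i = t.size
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD curvature in Laplace approximation")
    return (
        -0.5 * n_i * math.log(2.0 * math.pi * sigma2)
        - 0.5 * float(r @ r) / sigma2
        - 0.5 * float(b @ psi_inv @ b)
        - 0.5 * logdet_psi
        - 0.5 * logdet_H
    )


def _fixed_only_loglik(model, data, phi_per_patient, sigma2):
    """Gaussian log-likelihood with all random effects pinned at zero."""
    total = 0.0
    for (t, y), phi in zip(data, phi_per_patient):
        mu = mean_response(model, phi, t)
        r = y - mu
        total += -0.5 * t.size * math.log(2.0 * math.pi * sigma2) - 0.5 * float(
            r @ r
        ) / sigma2
    return total


def _phi_per_patient(model, theta, covariate_design, gamma, n_patients):
    """Per-patient fixed-effect parameter vectors (covariate shifts applied)."""
    base = np.asarray(theta, dtype=float)
    if covariate_design is None:
        return [base] * n_patients
    idx = model.param_index(covariate_design.placement)
    shifts = covariate_design.matrix @ np.asarray(gamma, dtype=float)
    out = []
    for i in range(n_patients):
        phi = base.copy()
        phi[idx] += shifts[i]
        out.append(phi)
    return out


def _psi_terms(psi, q):
    psi = np.asarray(psi, dtype=float).reshape(q, q)
    if not np.allclose(psi, psi.T):
        raise ValueError("psi must be symmetric")
    if np.all(psi == 0):
        return None, None  # degenerate: no random effects
    sign, logdet = np.linalg.slogdet(psi)
    if sign <= 0:
        raise np.linalg.LinAlgError("psi must be positive definite (or all zero)")
    return np.linalg.inv(psi), logdet


def marginal_loglik_laplace(
    model,
    re_spec: RandomEffectSpec,
    cohort: Cohort,
    theta,
    psi,
    sigma2: float,
    covariate_design: CovariateDesign | None = None,
    gamma=None,
    inner_tol: float = 1e-11,
    inner_maxiter: int = 50,
) -> float:
    """Laplace-approximated marginal log-likelihood of the whole cohort.

    ``theta`` is the natural-scale fixed-effect vector in the model's
    parameter order, ``psi`` the q x q random-effect covariance over
    ``re_spec.random_params`` and ``sigma2`` the residual variance. An
    all-zero ``psi`` is the degenerate no-random-effects limit and returns
    the plain fixed-effects Gaussian log-likelihood.
    """
    model = get_model(model) if isinstance(model, str) else model
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    data = _prepare(model, cohort)
    phi_all = _phi_per_patient(model, theta, covariate_design, gamma, len(data))
    psi_inv, logdet_psi = _psi_terms(psi, re_spec.q)
    if psi_inv is None:
        return _fixed_only_loglik(model, data, phi_all, sigma2)
    re_idx = [model.param_index(p) for p in re_spec.random_params]
    linear_in_b = _is_linear_in_b(model, re_spec.random_params)
    total = 0.0
    for (t, y), phi in zip(data, phi_all):
        total += _patient_laplace(
            model, t, y, phi, re_idx, psi_inv, logdet_psi, sigma2,
            linear_in_b, inner_tol, inner_maxiter,
        )
    return total


def marginal_loglik_quadrature(
    model,
    re_spec: RandomEffectSpec,
    cohort: Cohort,
    theta,
    psi,
    sigma2: float,
    n_nodes: int = 21,
    covariate_design: CovariateDesign | None = None,
    gamma=None,
) -> float:
    """Adaptive Gauss-Hermite quadrature over the random effects (<= 2 of them).

    Tensor-product rule recentered and rescaled at each patient's
    conditional mode; converges to the exact marginal log-likelihood as
    ``n_nodes`` grows. Serves as the brute-force oracle for the Laplace
    approximation.
    """
    model = get_model(model) if isinstance(model, str) else model
    if re_spec.q > 2:
        raise ValueError("quadrature oracle supports at most 2 random effects")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    data = _prepare(model, cohort)
    phi_all = _phi_per_patient(model, theta, covariate_design, gamma, len(data))
    psi_inv, logdet_psi = _psi_terms(psi, re_spec.q)
    if psi_inv is None:
        return _fixed_only_loglik(model, data, phi_all, sigma2)
    re_idx = [model.param_index(p) for p in re_spec.random_params]
    linear_in_b = _is_linear_in_b(model, re_spec.random_params)
    q = re_spec.q

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    if q == 1:
        Z = nodes[:, None]
        logW = np.log(weights)
    else:
        Z = np.array([[z1, z2] for z1 in nodes for z2 in nodes])
        logW = np.add.outer(np.log(weights), np.log(weights)).ravel()
    z_sq = np.sum(Z**2, axis=1)

    total = 0.0
    for (t, y), phi_base in zip(data, phi_all):
        b_hat, H, _, _ = _inner_mode(
            model, t, y, phi_base, re_idx, psi_inv, sigma2, linear_in_b
        )
        L = np.linalg.cholesky(np.linalg.inv(H))
        logdet_L = float(np.sum(np.log(np.diag(L))))
        n_i = t.size
        const = (
            -0.5 * n_i * math.log(2.0 * math.pi * sigma2)
            - 0.5 * q * math.log(2.0 * math.pi)
            - 0.5 * logdet_psi
        )
        vals = np.full(Z.shape[0], -np.inf)
        for k_node in range(Z.shape[0]):
            b = b_hat + math.sqrt(2.0) * (L @ Z[k_node])
            try:
                pen, _, _ = _penalized_sse(
                    model, t, y, phi_base, re_idx, b, psi_inv, sigma2
                )
            except GrowthModelDomainError:
                continue  # integrand is zero outside the domain
            vals[k_node] = const - 0.5 * pen + z_sq[k_node] + logW[k_node]
        m = np.max(vals)
        log_sum = m + math.log(np.sum(np.exp(vals - m)))
        total += 0.5 * q * math.log(2.0) + logdet_L + log_sum
    return total


# ---------------------------------------------------------------------------
# information criteria


def information_criteria(loglik: float, k: int, n_obs: int) -> tuple[float, float]:
    """AIC = 2k - 2 loglik; BIC = k ln(n_obs) - 2 loglik."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n_obs) - 2.0 * loglik
    return aic, bic


# ---------------------------------------------------------------------------
# parameter packing for the outer optimization


class _Packer:
    """Maps (theta, gamma, Psi, sigma2) to an unconstrained vector.

    Positive natural parameters travel as logs; Psi as a log-Cholesky
    factor (diagonal entries as logs) so it stays positive definite at
    every iterate; sigma2 as log sigma2.
    """

    def __init__(self, model: GrowthModel, re_spec: RandomEffectSpec, n_cov: int):
        self.model = model
        self.re_spec = re_spec
        self.n_cov = n_cov
        self.n_theta = model.n_params
        self.q = re_spec.q
        self.n_psi = re_spec.n_cov_params
        self.pos_idx = [model.param_index(p) for p in model.positive_params]
        self.size = self.n_theta + n_cov + self.n_psi + 1

    def pack(self, theta, gamma, psi, sigma2) -> np.ndarray:
        v = np.empty(self.size)
        th = np.asarray(theta, dtype=float).copy()
        th[self.pos_idx] = np.log(th[self.pos_idx])
        v[: self.n_theta] = th
        v[self.n_theta : self.n_theta + self.n_cov] = gamma
        L = np.linalg.cholesky(psi)
        if self.re_spec.covariance == "diagonal":
            chol_part = np.log(np.diag(L))
        else:
            entries = []
            for i in range(self.q):
                for j in range(i + 1):
                    entries.append(math.log(L[i, i]) if i == j else L[i, j])
            chol_part = np.array(entries)
        v[self.n_theta + self.n_cov : self.n_theta + self.n_cov + self.n_psi] = chol_part
        v[-1] = math.log(sigma2)
        return v

    def unpack(self, v: np.ndarray):
        th = v[: self.n_theta].copy()
        th[self.pos_idx] = np.exp(th[self.pos_idx])
        gamma = v[self.n_theta : self.n_theta + self.n_cov].copy()
        chol_part = v[self.n_theta + self.n_cov : self.n_theta + self.n_cov + self.n_psi]
        L = np.zeros((self.q, self.q))
        if self.re_spec.covariance == "diagonal":
            np.fill_diagonal(L, np.exp(chol_part))
        else:
            pos = 0
            for i in range(self.q):
                for j in range(i + 1):
                    L[i, j] = math.exp(chol_part[pos]) if i == j else chol_part[pos]
                    pos += 1
        psi = L @ L.T
        sigma2 = math.exp(v[-1])
        return th, gamma, psi, sigma2


# ---------------------------------------------------------------------------
# starting values


def _per_patient_estimates(model: GrowthModel, data):
    """Crude per-patient curve-fit estimates used only as starting values."""
    if model.name in ("linear", "exponential"):
        est = []
        for t, y in data:
            slope, intercept = np.polyfit(t, y, 1)
            est.append((intercept, slope))
        return np.array(est), None
    if model.name == "radial":
        est = []
        for t, y in data:
            r = np.cbrt(3.0 * np.exp(y) / (4.0 * np.pi))
            slope, intercept = np.polyfit(t, r, 1)
            est.append((max(intercept, 1e-3), slope))
        return np.array(est), None
    # gompertz: profile a small alpha grid, per-patient OLS on the induced basis
    alphas = np.array([0.0025, 0.005, 0.01, 0.02, 0.04, 0.08, 0.16])
    best = None
    for alpha in alphas:
        sse = 0.0
        est = []
        ok = True
        for t, y in data:
            decay = np.exp(-alpha * t)
            X = np.column_stack([1.0 - decay, decay])
            coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < 2:
                ok = False
                break
            sse += float(np.sum((y - X @ coef) ** 2))
            est.append((coef[0], coef[1], alpha))  # (log_k, log_v0, alpha)
        if ok and (best is None or sse < best[0]):
            best = (sse, np.array(est), alpha)
    if best is None:
        raise RuntimeError("could not build Gompertz starting values")
    return best[1], best[2]


def _initial_values(model: GrowthModel, re_spec: RandomEffectSpec, data, n_cov):
    est, _ = _per_patient_estimates(model, data)
    # winsorize the crude estimates so a few wild patients cannot ruin the start
    lo = np.percentile(est, 5, axis=0)
    hi = np.percentile(est, 95, axis=0)
    est_w = np.clip(est, lo, hi)
    theta = np.median(est_w, axis=0)
    if model.name == "gompertz" and theta[0] <= theta[1]:
        theta[0] = theta[1] + 0.5  # ensure a positive growth reserve at start
    for idx in [model.param_index(p) for p in model.positive_params]:
        theta[idx] = max(theta[idx], 1e-3)
    re_idx = [model.param_index(p) for p in re_spec.random_params]
    sub = est_w[:, re_idx]
    psi = np.cov(sub.T) if sub.shape[0] > 1 else np.eye(re_spec.q)
    psi = np.atleast_2d(psi)
    # regularize: floor the variances, cap correlations
    d = np.sqrt(np.clip(np.diag(psi), 1e-4, None))
    corr = psi / np.outer(d, d)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -0.95, 0.95)
    np.fill_diagonal(corr, 1.0)
    psi = corr * np.outer(d, d)
    if re_spec.covariance == "diagonal":
        psi = np.diag(np.diag(psi))
    # pooled residual variance from the per-patient fits
    sse, n_res = 0.0, 0
    for (t, y), e in zip(data, est):
        try:
            params = e[: model.n_params]
            if model.name in ("linear", "exponential"):
                params = np.array([e[0], e[1]])
            mu = mean_response(model, params, t)
            sse += float(np.sum((y - mu) ** 2))
            n_res += t.size
        except GrowthModelDomainError:
            continue
    sigma2 = max(sse / max(n_res, 1), 1e-4)
    gamma = np.zeros(n_cov)
    return theta, gamma, psi, sigma2


# ---------------------------------------------------------------------------
# fitting


def fit_nlme(
    model,
    re_spec: RandomEffectSpec | None,
    cohort: Cohort,
    config: FitConfig | None = None,
    covariate_design: CovariateDesign | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one growth law with patient random effects.

    Maximizes the Laplace-approximated marginal likelihood over the fixed
    effects, the random-effect covariance and the residual variance with
    multi-start L-BFGS (first start from per-patient curve-fit moments, the
    rest seeded perturbations). Deterministic given ``config.seed``.
    """
    model = get_model(model) if isinstance(model, str) else model
    if re_spec is None:
        re_spec = default_re_spec(model.name)
    if config is None:
        config = FitConfig()
    data = _prepare(model, cohort)
    n_obs = sum(t.size for t, _ in data)
    n_cov = 0 if covariate_design is None else len(covariate_design.names)
    if covariate_design is not None and covariate_design.matrix.shape[0] != len(data):
        raise ValueError("covariate design rows must match number of patients")
    packer = _Packer(model, re_spec, n_cov)
    re_idx = [model.param_index(p) for p in re_spec.random_params]
    linear_in_b = _is_linear_in_b(model, re_spec.random_params)

    def negll(v: np.ndarray) -> float:
        try:
            theta, gamma, psi, sigma2 = packer.unpack(v)
            phi_all = _phi_per_patient(
                model, theta, covariate_design, gamma, len(data)
            )
            psi_inv, logdet_psi = _psi_terms(psi, re_spec.q)
            total = 0.0
            for (t, y), phi in zip(data, phi_all):
                total += _patient_laplace(
                    model, t, y, phi, re_idx, psi_inv, logdet_psi, sigma2,
                    linear_in_b, config.inner_tol, config.inner_maxiter,
                )
            if not np.isfinite(total):
                return _BIG
            return -total
        except (GrowthModelDomainError, np.linalg.LinAlgError, OverflowError,
                FloatingPointError):
            return _BIG

    theta0, gamma0, psi0, sigma2_0 = _initial_values(model, re_spec, data, n_cov)
    x0 = packer.pack(theta0, gamma0, psi0, sigma2_0)
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(config.n_starts - 1):
        starts.append(x0 + rng.normal(0.0, config.perturb_scale, size=x0.size))

    best = None
    best_success = False
    n_iter_total = 0
    for start in starts:
        res = optimize.minimize(
            negll,
            start,
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        n_iter_total += res.nit
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success)
    if best is None:
        raise RuntimeError(f"{model.name}: all optimizer starts failed")
    any_success = best_success

    theta_hat, gamma_hat, psi_hat, sigma2_hat = packer.unpack(best.x)
    loglik = -float(best.fun)
    k = model.n_params + n_cov + re_spec.n_cov_params + 1
    aic, bic = information_criteria(loglik, k, n_obs)

    theta_names = list(model.param_names) + list(
        covariate_design.names if covariate_design else ()
    )
    theta_full = np.concatenate([theta_hat, gamma_hat])
    se = np.full(theta_full.size, np.nan)
    vcov = None
    if config.compute_se:
        se_full, vcov = _wald_se(
            negll_natural_factory(
                packer, model, negll_core_factory(
                    model, data, covariate_design, re_spec, re_idx, linear_in_b,
                    config,
                )
            ),
            np.concatenate([theta_hat, gamma_hat, best.x[packer.n_theta + n_cov:]]),
            n_free=theta_full.size,
        )
        se = se_full
    return FitResult(
        model=model.name,
        theta_hat=dict(zip(theta_names, theta_full.tolist())),
        se_theta=dict(zip(theta_names, se.tolist())),
        psi_hat=psi_hat,
        re_params=re_spec.random_params,
        sigma2_hat=float(sigma2_hat),
        loglik=loglik,
        k=k,
        n_obs=n_obs,
        n_patients=len(data),
        aic=aic,
        bic=bic,
        converged=bool(any_success),
        n_iter=int(n_iter_total),
        response_scale=model.response_scale,
        covariate_names=tuple(covariate_design.names) if covariate_design else (),
        vcov=vcov,
        param_order=tuple(theta_names),
    )


def negll_core_factory(model, data, covariate_design, re_spec, re_idx,
                       linear_in_b, config):
    """Negative log-likelihood as a function of natural-scale pieces."""

    def core(theta, gamma, psi, sigma2):
        try:
            phi_all = _phi_per_patient(
                model, theta, covariate_design, gamma, len(data)
            )
            psi_inv, logdet_psi = _psi_terms(psi, re_spec.q)
            total = 0.0
            for (t, y), phi in zip(data, phi_all):
                total += _patient_laplace(
                    model, t, y, phi, re_idx, psi_inv, logdet_psi, sigma2,
                    linear_in_b, config.inner_tol, config.inner_maxiter,
                )
            return -total if np.isfinite(total) else _BIG
        except (GrowthModelDomainError, np.linalg.LinAlgError, OverflowError,
                FloatingPointError):
            return _BIG

    return core


def negll_natural_factory(packer: _Packer, model, core):
    """Negative log-likelihood over (natural theta+gamma, packed psi, log s2).

    The fixed effects travel on their natural scale here so the observed
    information directly yields Wald standard errors without a delta step.
    """
    n_free = packer.n_theta + packer.n_cov

    def f(v):
        theta = v[: packer.n_theta]
        gamma = v[packer.n_theta : n_free]
        tail = np.concatenate([np.zeros(n_free), v[n_free:]])
        _, _, psi, sigma2 = packer.unpack(tail)
        if np.any(theta[packer.pos_idx] <= 0):
            return _BIG
        return core(theta, gamma, psi, sigma2)

    return f


def _wald_se(f, x, n_free):
    """Standard errors from the inverse numerical observed information.

    Central-difference Hessian of the negative log-likelihood over all
    parameters jointly; the reported SEs are the square roots of the
    fixed-effect diagonal of its inverse.
    """
    p = x.size
    h = 1e-4 * np.maximum(np.abs(x), 0.1)
    f0 = f(x)
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(p):
        for j in range(i):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)[:n_free]
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(diag), cov[:n_free, :n_free]
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        diag = np.abs(np.diag(cov)[:n_free])
        return np.sqrt(diag), cov[:n_free, :n_free]


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    cohort: Cohort,
    models=("linear", "exponential", "radial", "gompertz"),
    re_specs: dict | None = None,
    config: FitConfig | None = None,
    jacobian_correction: bool = False,
) -> pd.DataFrame:
    """Fit several growth laws and rank them by AIC (goodness-of-fit table).

    Each model is scored on its own response scale by default, so the
    volume-scale linear law and the log-scale laws are not on a common
    likelihood scale; set ``jacobian_correction=True`` for an extra column
    with all log-likelihoods transported to the volume scale
    (subtracting sum(log V) from the log-scale models).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    re_specs = re_specs or {}
    rows = []
    sum_log_v = float(
        sum(np.sum(np.log(p.volumes)) for p in cohort)
    )
    for name in models:
        spec = re_specs.get(name, default_re_spec(name))
        try:
            fit = fit_nlme(name, spec, cohort, config=config)
            row = {
                "model": name,
                "response_scale": fit.response_scale,
                "loglik": fit.loglik,
                "k": fit.k,
                "n_obs": fit.n_obs,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
            }
            if jacobian_correction:
                row["loglik_volume_scale"] = (
                    fit.loglik - sum_log_v
                    if fit.response_scale == "log_volume"
                    else fit.loglik
                )
        except RuntimeError as exc:
            row = {
                "model": name,
                "response_scale": get_model(name).response_scale,
                "loglik": np.nan,
                "k": np.nan,
                "n_obs": np.nan,
                "aic": np.inf,
                "bic": np.inf,
                "converged": False,
                "error": str(exc),
            }
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["aic", "model"], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
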