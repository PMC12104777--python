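"""Variational-Laplace model inversion.

Fits a fixed-form Gaussian approximate posterior over the unconstrained
parameters together with a Gaussian posterior over the observation-noise
log-precision, by Gauss-Newton ascent on the free energy with
Levenberg-Marquardt damping.  The free energy decomposes as

    F = accuracy - KL(q(theta) || p(theta)) - KL(q(lambda) || p(lambda))

and approximates the log marginal evidence at convergence.  For linear
forward models with fixed noise precision the optimum coincides with the
conjugate Gaussian closed form and F equals the exact log evidence.

Also provides Gaussian Bayesian model reduction: the posterior and
evidence change implied by swapping the prior of an already-fitted model,
computed analytically from the Gaussian posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg

from . import model as mdl
from .exceptions import DimensionError, NumericalError, ValidationError
from .model import FrequencyGrid, ModelSpec, PriorSpec

__all__ = [
    "FitOptions",
    "Posterior",
    "fit",
    "fit_forward",
    "spectral_forward",
    "jacobian",
    "free_energy",
    "gaussian_kl",
    "bmr_reduce",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitOptions:
    """Optimiser settings for variational-Laplace fits."""

    max_iter: int = 128
    tol_df: float = 1e-3
    damping_init: float = 1e-2
    damping_up: float = 8.0
    damping_down: float = 2.0
    jacobian: str = "analytic"  # or "finite_diff"
    fd_step: float = 1e-4
    update_lambda: bool = True
    init: np.ndarray | None = None  # starting point; defaults to the prior mean

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol_df <= 0:
            raise ValidationError("tol_df must be > 0")
        if self.jacobian not in ("analytic", "finite_diff"):
            raise ValidationError("jacobian must be 'analytic' or 'finite_diff'")


@dataclass
class Posterior:
    """Gaussian approximate posterior plus free-energy decomposition."""

    mean: np.ndarray
    cov: np.ndarray
    lambda_mean: float
    lambda_var: float
    free_energy: float
    accuracy: float
    complexity_theta: float
    complexity_lambda: float
    n_iter: int
    converged: bool
    prior: PriorSpec | None = None
    scale_factor: float = 1.0
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "lambda_mean": self.lambda_mean,
            "lambda_var": self.lambda_var,
            "free_energy": self.free_energy,
            "accuracy": self.accuracy,
            "complexity_theta": self.complexity_theta,
            "complexity_lambda": self.complexity_lambda,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "scale_factor": self.scale_factor,
        }


def gaussian_kl(m1, C1, m0, C0) -> float:
    """KL divergence KL(N(m1, C1) || N(m0, C0))."""
    m1 = np.atleast_1d(np.asarray(m1, dtype=float))
    m0 = np.atleast_1d(np.asarray(m0, dtype=float))
    C1 = np.atleast_2d(np.asarray(C1, dtype=float))
    C0 = np.atleast_2d(np.asarray(C0, dtype=float))
    p = m1.size
    L0 = linalg.cholesky(C0, lower=True)
    d = m1 - m0
    sol = linalg.cho_solve((L0, True), C1)
    quad = d @ linalg.cho_solve((L0, True), d)
    _, ld1 = np.linalg.slogdet(C1)
    ld0 = 2.0 * np.sum(np.log(np.diag(L0)))
    kl = 0.5 * (np.trace(sol) + quad - p + ld0 - ld1)
    return float(max(kl, 0.0))


def _kl_scalar(m1: float, v1: float, m0: float, v0: float) -> float:
    if v1 <= 0:
        # degenerate (fixed) hyperparameter: no complexity charged
        return 0.0
    kl = 0.5 * (v1 / v0 + (m1 - m0) ** 2 / v0 - 1.0 + np.log(v0 / v1))
    return float(max(kl, 0.0))


def spectral_forward(
    spec: ModelSpec, grid: FrequencyGrid
) -> Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Build ``theta -> (prediction, jacobian)`` for a spectral model.

    Handles link functions, filters, the amplitude/log domain and
    condition designs (per-condition predictions are stacked).
    """
    f = grid.freqs
    logf = np.log(f)
    mult = mdl.combined_filter_response(spec.filters, grid, spec.filter_mode)

    def _one(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nat = mdl.apply_links(theta, spec.bands)
        n, p = f.size, theta.size
        J = np.zeros((n, p))
        aperiodic = nat.gamma * np.exp(nat.alpha * logf)
        if spec.domain == "log":
            s = np.log(aperiodic)
            J[:, mdl.IDX_GAMMA] = 1.0
            J[:, mdl.IDX_ALPHA] = nat.alpha * logf
        else:
            s = aperiodic.copy()
            J[:, mdl.IDX_GAMMA] = aperiodic
            J[:, mdl.IDX_ALPHA] = aperiodic * logf * nat.alpha
        for i, band in enumerate(spec.bands):
            h, m, w = nat.h[i], nat.m[i], nat.s[i]
            z = (f - m) / w
            G = np.exp(-0.5 * z * z)
            sl = mdl.band_slice(i)
            sig = mdl.softclip_sigmoid(theta[sl][1])
            dm_dtheta = sig * (1.0 - sig) * band.width
            J[:, sl.start] = h * G
            J[:, sl.start + 1] = h * G * (f - m) / (w * w) * dm_dtheta
            J[:, sl.start + 2] = h * G * z * z
            s += h * G
        if mult is not None:
            if spec.domain == "log":
                s = s + np.log(np.maximum(mult, 1e-12))
            else:
                s = mult * s
                J = mult[:, None] * J
        return s, J

    design = spec.condition_design
    if design is None:
        return _one

    def _stacked(theta_full: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        preds, jacs = [], []
        for X in design.matrices:
            s_c, J_c = _one(X @ theta_full)
            preds.append(s_c)
            jacs.append(J_c @ X)
        return np.concatenate(preds), np.vstack(jacs)

    return _stacked


def jacobian(
    raw, spec: ModelSpec, grid: FrequencyGrid, method: str = "analytic", fd_step: float = 1e-4
) -> np.ndarray:
    """Derivative of the (stacked) model prediction wrt the unconstrained parameters."""
    raw = np.asarray(raw, dtype=float).ravel()
    fwd = spectral_forward(spec, grid)
    if method == "analytic":
        return fwd(raw)[1]
    return _fd_jacobian(fwd, raw, fd_step)


def _fd_jacobian(forward, theta: np.ndarray, step: float) -> np.ndarray:
    cols = []
    for j in range(theta.size):
        e = np.zeros_like(theta)
        e[j] = step
        sp = forward(theta + e)[0]
        sm = forward(theta - e)[0]
        cols.append((sp - sm) / (2.0 * step))
    return np.stack(cols, axis=1)


def free_energy(
    resid: np.ndarray,
    J: np.ndarray,
    Sigma: np.ndarray,
    lam_mean: float,
    lam_var: float,
    mu: np.ndarray,
    priors: PriorSpec,
    logdet_R: float = 0.0,
) -> tuple[float, float, float, float]:
    """Free energy and its accuracy/complexity decomposition.

    ``resid`` and ``J`` are assumed pre-whitened when the noise
    correlation is not the identity (``logdet_R`` carries the constant).
    """
    n = resid.size
    elam = np.exp(lam_mean)
    err = float(resid @ resid + np.sum((J @ Sigma) * J))
    accuracy = -0.5 * n * _LOG2PI + 0.5 * n * lam_mean - 0.5 * logdet_R - 0.5 * elam * err
    c_theta = gaussian_kl(mu, Sigma, priors.mean, priors.cov)
    c_lambda = _kl_scalar(lam_mean, lam_var, priors.hyper_mean, priors.hyper_var)
    F = accuracy - c_theta - c_lambda
    return float(F), float(accuracy), c_theta, c_lambda


class _State:
    """Cached quantities at one (mu, lam) point."""

    __slots__ = ("mu", "lam", "s", "J", "r", "H", "Sigma", "err", "vlam", "F",
                 "accuracy", "c_theta", "c_lambda", "g")


def fit_forward(
    y,
    forward: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    priors: PriorSpec,
    opts: FitOptions | None = None,
) -> Posterior:
    """Variational-Laplace fit for an arbitrary differentiable forward model.

    ``forward(theta)`` must return ``(prediction, jacobian)``.  The noise
    correlation is the identity; pre-whiten data and forward model for
    correlated noise.
    """
    opts = opts or FitOptions()
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValidationError("data contain non-finite values")
    mu0 = priors.mean
    p = mu0.size
    P0 = np.linalg.inv(priors.cov)
    hv = priors.hyper_var
    update_lam = opts.update_lambda and hv > 0
    n = y.size

    def evaluate(mu: np.ndarray, lam: float) -> _State:
        st = _State()
        st.mu = mu
        st.lam = lam
        st.s, st.J = forward(mu)
        if st.s.size != n:
            raise DimensionError(
                f"forward model returned {st.s.size} values for {n} data points"
            )
        st.r = y - st.s
        elam = np.exp(lam)
        H = elam * (st.J.T @ st.J) + P0
        H = 0.5 * (H + H.T)
        try:
            c, low = linalg.cho_factor(H)
        except linalg.LinAlgError:
            try:
                c, low = linalg.cho_factor(H + 1e-8 * np.eye(p))
            except linalg.LinAlgError as e:
                raise NumericalError("singular curvature despite damping") from e
        st.H = H
        st.Sigma = linalg.cho_solve((c, low), np.eye(p))
        st.err = float(st.r @ st.r + np.sum((st.J @ st.Sigma) * st.J))
        st.vlam = 1.0 / (0.5 * elam * st.err + 1.0 / hv) if update_lam else 0.0
        st.g = elam * (st.J.T @ st.r) - P0 @ (mu - mu0)
        st.F, st.accuracy, st.c_theta, st.c_lambda = free_energy(
            st.r, st.J, st.Sigma, lam, st.vlam, mu, priors
        )
        return st

    def newton_lambda(mu: np.ndarray, lam: float) -> float:
        if not update_lam:
            return lam
        for _ in range(8):
            st = evaluate(mu, lam)
            elam = np.exp(lam)
            grad = 0.5 * n - 0.5 * elam * st.err - (lam - priors.hyper_mean) / hv
            hess = -0.5 * elam * st.err - 1.0 / hv
            step = float(np.clip(-grad / hess, -4.0, 4.0))
            lam += step
            if abs(step) < 1e-6:
                break
        return lam

    if opts.init is not None:
        mu = np.asarray(opts.init, dtype=float).ravel().copy()
        if mu.size != p:
            raise DimensionError(f"init has length {mu.size}, expected {p}")
    else:
        mu = mu0.copy()
    lam = priors.hyper_mean
    lam = newton_lambda(mu, lam)
    state = evaluate(mu, lam)
    damping = opts.damping_init
    trace = [state.F]
    converged = False
    n_small = 0
    it = 0
    for it in range(1, opts.max_iter + 1):
        accepted = False
        d = damping
        while d <= 1e12:
            Hd = state.H + d * np.diag(np.diag(state.H)) + 1e-12 * np.eye(p)
            try:
                dmu = np.linalg.solve(Hd, state.g)
            except np.linalg.LinAlgError:
                d *= opts.damping_up
                continue
            mu_try = state.mu + dmu
            lam_try = newton_lambda(mu_try, state.lam)
            try:
                st_try = evaluate(mu_try, lam_try)
            except (NumericalError, FloatingPointError):
                d *= opts.damping_up
                continue
            if np.isfinite(st_try.F) and st_try.F > state.F:
                dF = st_try.F - state.F
                state = st_try
                damping = max(d / opts.damping_down, 1e-8)
                accepted = True
                trace.append(state.F)
                break
            d *= opts.damping_up
        if not accepted:
            # no ascent direction improves F: already at a (local) optimum
            converged = True
            break
        n_small = n_small + 1 if abs(dF) < opts.tol_df else 0
        if n_small >= 3:
            converged = True
            break

    return Posterior(
        mean=state.mu,
        cov=state.Sigma,
        lambda_mean=state.lam,
        lambda_var=state.vlam,
        free_energy=state.F,
        accuracy=state.accuracy,
        complexity_theta=state.c_theta,
        complexity_lambda=state.c_lambda,
        n_iter=it,
        converged=converged,
        prior=priors,
        trace=trace,
    )


def fit(
    y,
    grid: FrequencyGrid,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    opts: FitOptions | None = None,
) -> Posterior:
    """Invert a spectral model on observed spectra.

    ``y`` is a vector of length ``len(grid)``, or an array of shape
    ``(n_conditions, len(grid))`` when the spec carries a condition
    design (rows are stacked into one augmented likelihood with a shared
    noise log-precision).
    """
    opts = opts or FitOptions()
    priors = priors if priors is not None else mdl.default_priors(spec)
    if priors.n_params != spec.n_params_full:
        raise DimensionError(
            f"priors cover {priors.n_params} parameters, model has {spec.n_params_full}"
        )
    y = np.asarray(y, dtype=float)
    design = spec.condition_design
    if design is not None:
        if y.ndim != 2 or y.shape != (design.n_conditions, len(grid)):
            raise DimensionError(
                f"expected data of shape ({design.n_conditions}, {len(grid)})"
            )
        y = y.ravel()
    else:
        y = y.ravel()
        if y.size != len(grid):
            raise DimensionError(f"data length {y.size} does not match grid length {len(grid)}")
    forward = spectral_forward(spec, grid)
    if opts.jacobian == "finite_diff":
        base = forward
        step = opts.fd_step

        def forward_fd(theta):
            s, _ = base(theta)
            return s, _fd_jacobian(lambda t: base(t), theta, step)

        return fit_forward(y, forward_fd, priors, opts)
    return fit_forward(y, forward, priors, opts)


def bmr_reduce(
    post: Posterior, prior: PriorSpec, reduced_prior: PriorSpec
) -> tuple[Posterior, float]:
    """Gaussian Bayesian model reduction.

    Given a posterior obtained under ``prior``, returns the posterior and
    log-evidence change implied by swapping in ``reduced_prior`` (same
    dimension, different mean/covariance), computed analytically.
    """
    if reduced_prior.n_params != prior.n_params:
        raise DimensionError("reduced prior must have the same dimension as the full prior")
    P = np.linalg.inv(post.cov)
    P0 = np.linalg.inv(prior.cov)
    P0r = np.linalg.inv(reduced_prior.cov)
    Pr = P + P0r - P0
    Pr = 0.5 * (Pr + Pr.T)
    try:
        linalg.cholesky(Pr, lower=True)
    except linalg.LinAlgError as e:
        raise NumericalError("reduced posterior precision is not positive definite") from e
    mu, mu0, mu0r = post.mean, prior.mean, reduced_prior.mean
    b = P @ mu + P0r @ mu0r - P0 @ mu0
    mur = np.linalg.solve(Pr, b)
    sld = np.linalg.slogdet
    dF = 0.5 * (sld(P)[1] - sld(Pr)[1] + sld(P0r)[1] - sld(P0)[1]) + 0.5 * (
        mur @ Pr @ mur - mu @ P @ mu + mu0 @ P0 @ mu0 - mu0r @ P0r @ mu0r
    )
    dF = float(dF)
    cov_r = np.linalg.inv(Pr)
    cov_r = 0.5 * (cov_r + cov_r.T)
    c_theta = gaussian_kl(mur, cov_r, mu0r, reduced_prior.cov)
    F_r = post.free_energy + dF
    reduced = Posterior(
        mean=mur,
        cov=cov_r,
        lambda_mean=post.lambda_mean,
        lambda_var=post.lambda_var,
        free_energy=F_r,
        # accuracy implied so that F = accuracy - complexities still holds
        accuracy=F_r + c_theta + post.complexity_lambda,
        complexity_theta=c_theta,
        complexity_lambda=post.complexity_lambda,
        n_iter=post.n_iter,
        converged=post.converged,
        prior=reduced_prior,
        scale_factor=post.scale_factor,
    )
    return reduced, dF
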