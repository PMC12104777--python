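"""Parametric empirical Bayes: second-level GLM over first-level posteriors.

Subject-level unconstrained parameters are modelled as

    theta_k = B @ x_k + e_k,      e_k ~ N(0, Q(gamma))

where ``x_k`` is the subject's row of the group design matrix, ``B`` is
the (parameters x regressors) matrix of group coefficients, and the
random-effects covariance ``Q`` is diagonal with one log-precision per
first-level parameter.  Given the log-precisions, each subject's
contribution to the hierarchical evidence is obtained by Bayesian model
reduction (swapping the subject's fitting prior for the implied
second-level prior), which is quadratic in ``B`` so the posterior over
the group coefficients is available in closed form.  The log-precisions
are optimised numerically to maximise the hierarchical free energy under
standard-normal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from . import model as mdl
from .exceptions import DimensionError, ValidationError
from .inversion import Posterior
from .model import FrequencyGrid, ModelSpec, PriorSpec

__all__ = [
    "GroupDesign",
    "GroupPosterior",
    "CredibleBand",
    "peb_fit",
    "credible_band",
    "interpolate_group_spectrum",
]


@dataclass
class GroupDesign:
    """Second-level design matrix (subjects x regressors).

    Non-intercept columns are mean-centered by default so the intercept
    is the group average; the offsets are kept for mapping covariate
    values at prediction time.
    """

    X2: np.ndarray
    names: list[str] = field(default_factory=list)
    center: bool = True
    offsets: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X2, dtype=float))
        if X.ndim != 2:
            raise DimensionError("design matrix must be 2-D")
        if not self.names:
            self.names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
        if len(self.names) != X.shape[1]:
            raise DimensionError("number of regressor names must match design columns")
        if self.offsets is None:
            offsets = np.zeros(X.shape[1])
            if self.center and X.shape[1] > 1:
                offsets[1:] = X[:, 1:].mean(axis=0)
                X = X.copy()
                X[:, 1:] -= offsets[1:]
            self.offsets = offsets
        self.X2 = X
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("design matrix is rank deficient")
        if X.shape[1] > 1 and X.shape[0] < 2:
            raise ValidationError("at least 2 subjects are required with a covariate")

    @property
    def n_subjects(self) -> int:
        return self.X2.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X2.shape[1]


@dataclass
class GroupPosterior:
    """Posterior over second-level coefficients."""

    beta_mean: np.ndarray  # (n_params, n_regressors)
    beta_cov: np.ndarray  # (n_params*n_regressors,) square, row-major over beta
    gamma2_mean: np.ndarray  # per-parameter random-effects log-precision (MAP)
    gamma2_var: np.ndarray
    F_total: float
    design: GroupDesign = None
    param_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.F_total):
            raise ValidationError("hierarchical free energy must be finite")

    def to_dict(self) -> dict:
        return {
            "beta_mean": self.beta_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "gamma2_mean": self.gamma2_mean.tolist(),
            "gamma2_var": self.gamma2_var.tolist(),
            "F_total": self.F_total,
            "regressors": self.design.names if self.design else None,
            "param_names": self.param_names,
        }


@dataclass
class CredibleBand:
    """Pointwise credible band of one parameter over a covariate range."""

    covariate: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    param_index: int

    def __post_init__(self):
        if np.any(self.lower > self.mean + 1e-12) or np.any(self.mean > self.upper + 1e-12):
            raise ValidationError("credible band must satisfy lower <= mean <= upper")


def _subject_moments(posteriors: Sequence[Posterior], priors: PriorSpec):
    p = priors.n_params
    mus, Ps, cs = [], [], []
    P0 = np.linalg.inv(priors.cov)
    for post in posteriors:
        if post.mean.size != p:
            raise DimensionError("all subject posteriors must share the parameter dimension")
        Pk = np.linalg.inv(post.cov)
        mus.append(post.mean)
        Ps.append(Pk)
        cs.append(Pk @ post.mean - P0 @ priors.mean)
    return mus, Ps, cs, P0


def peb_fit(
    posteriors: Sequence[Posterior],
    priors: PriorSpec,
    design: GroupDesign,
    beta_prior_scale: float = 1.0,
    gamma_prior_var: float = 1.0,
    fix_gamma: np.ndarray | None = None,
    param_names: list[str] | None = None,
) -> GroupPosterior:
    """Fit the second-level GLM by maximising the hierarchical free energy.

    ``priors`` is the first-level prior the subject posteriors were
    fitted under.  Noise log-precisions are not part of the second level;
    only the unconstrained spectral parameters are modelled.
    """
    K = len(posteriors)
    if K != design.n_subjects:
        raise DimensionError(
            f"{K} posteriors but design has {design.n_subjects} rows"
        )
    mus, Ps, cs, P0 = _subject_moments(posteriors, priors)
    p = priors.n_params
    R = design.n_regressors
    X = design.X2

    # prior over vec(B) (row-major: parameter-major, regressor-minor):
    # intercept columns centred on the first-level prior mean, covariate
    # columns on zero, variances inherited from the first-level prior.
    u0 = np.zeros(p * R)
    var_u = np.zeros(p * R)
    diag0 = np.diag(priors.cov)
    for i in range(p):
        for j in range(R):
            idx = i * R + j
            u0[idx] = priors.mean[i] if j == 0 else 0.0
            var_u[idx] = beta_prior_scale * diag0[i]
    Pb0 = np.diag(1.0 / var_u)
    ld_Pb0 = float(np.sum(np.log(1.0 / var_u)))

    sld = np.linalg.slogdet
    ld_P0 = sld(P0)[1]
    ld_Pk = [sld(Pk)[1] for Pk in Ps]
    quad_k = [float(mu @ Pk @ mu) for mu, Pk in zip(mus, Ps)]
    quad_0 = float(priors.mean @ P0 @ priors.mean)

    def evidence(gamma: np.ndarray):
        """Log evidence of the hierarchy marginalised over B, given gamma."""
        qi = np.exp(np.clip(gamma, -40.0, 40.0))  # Q^{-1} diagonal
        A = Pb0.copy()
        b = Pb0 @ u0
        const = -0.5 * np.sum(u0 * (Pb0 @ u0)) + 0.5 * ld_Pb0
        for k in range(K):
            Prk = Ps[k] + np.diag(qi) - P0
            Prk = 0.5 * (Prk + Prk.T)
            try:
                ch = linalg.cho_factor(Prk)
            except linalg.LinAlgError:
                return None
            Prk_inv = linalg.cho_solve(ch, np.eye(p))
            ld_Prk = 2.0 * float(np.sum(np.log(np.diag(ch[0]))))
            # data precision for the implied prior mean m_k = B x_k
            D = np.diag(qi) - (qi[:, None] * Prk_inv) * qi[None, :]
            D = 0.5 * (D + D.T)
            x = X[k]
            # vec(B) row-major: contribution kron over (param, regressor)
            A += np.kron(D, np.outer(x, x))
            v = qi * (Prk_inv @ cs[k])
            b += np.kron(v, x)
            const += 0.5 * (ld_Pk[k] - ld_P0 - ld_Prk + float(np.sum(gamma)))
            const += -0.5 * quad_k[k] + 0.5 * quad_0
            const += 0.5 * float(cs[k] @ (Prk_inv @ cs[k]))
        A = 0.5 * (A + A.T)
        try:
            chA = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return None
        u_hat = linalg.cho_solve(chA, b)
        ld_A = 2.0 * float(np.sum(np.log(np.diag(chA[0]))))
        F = const + 0.5 * float(b @ u_hat) - 0.5 * ld_A
        return F, u_hat, A, chA

    def log_gamma_prior(gamma: np.ndarray) -> float:
        return float(-0.5 * np.sum(gamma ** 2) / gamma_prior_var
                     - 0.5 * gamma.size * np.log(2 * np.pi * gamma_prior_var))

    def objective(gamma: np.ndarray) -> float:
        out = evidence(gamma)
        if out is None:
            return 1e10
        return -(out[0] + log_gamma_prior(gamma))

    if fix_gamma is not None:
        gamma_hat = np.broadcast_to(np.asarray(fix_gamma, dtype=float), (p,)).copy()
    else:
        res = optimize.minimize(
            objective, np.zeros(p), method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-10},
        )
        gamma_hat = res.x
    out = evidence(gamma_hat)
    if out is None:
        raise ValidationError("hierarchical evidence is not defined at the optimum")
    F, u_hat, A, chA = out
    F_total = float(F + log_gamma_prior(gamma_hat))
    beta_cov = linalg.cho_solve(chA, np.eye(p * R))
    beta_cov = 0.5 * (beta_cov + beta_cov.T)

    # Laplace variance of the log-precisions from a diagonal numeric Hessian
    gvar = np.zeros(p)
    if fix_gamma is None:
        h = 1e-3
        f0 = objective(gamma_hat)
        for i in range(p):
            e = np.zeros(p)
            e[i] = h
            d2 = (objective(gamma_hat + e) - 2 * f0 + objective(gamma_hat - e)) / h ** 2
            gvar[i] = 1.0 / d2 if d2 > 1e-12 else gamma_prior_var

    return GroupPosterior(
        beta_mean=u_hat.reshape(p, R),
        beta_cov=beta_cov,
        gamma2_mean=gamma_hat,
        gamma2_var=gvar,
        F_total=F_total,
        design=design,
        param_names=param_names or [f"theta{i}" for i in range(p)],
    )


def credible_band(
    group: GroupPosterior,
    param_index: int,
    covariate: np.ndarray,
    level: float = 0.90,
    link: Callable[[np.ndarray], np.ndarray] | None = None,
    regressor: int = 1,
) -> CredibleBand:
    """Pointwise credible band for one parameter along a covariate.

    The linear predictor combines the intercept and the chosen regressor
    (on its original scale; centering offsets are handled internally).
    A monotone ``link`` maps the band to the natural scale; quantiles are
    preserved, with endpoints reordered for decreasing links.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("credible level must be in (0, 1)")
    p, R = group.beta_mean.shape
    if not 0 <= param_index < p:
        raise KeyError(f"unknown parameter index {param_index}")
    if not 0 <= regressor < R:
        raise KeyError(f"unknown regressor index {regressor}")
    covariate = np.asarray(covariate, dtype=float).ravel()
    off = group.design.offsets[regressor] if group.design is not None else 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    idx = [param_index * R + 0, param_index * R + regressor]
    C = group.beta_cov[np.ix_(idx, idx)]
    b0 = group.beta_mean[param_index, 0]
    b1 = group.beta_mean[param_index, regressor]
    mean = np.empty_like(covariate)
    lo = np.empty_like(covariate)
    hi = np.empty_like(covariate)
    for i, x in enumerate(covariate):
        w = np.array([1.0, x - off])
        eta = b0 + b1 * (x - off)
        sd = float(np.sqrt(max(w @ C @ w, 0.0)))
        mean[i] = eta
        lo[i] = eta - z * sd
        hi[i] = eta + z * sd
    if link is not None:
        mean = np.asarray(link(mean), dtype=float)
        a = np.asarray(link(lo), dtype=float)
        b = np.asarray(link(hi), dtype=float)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
    return CredibleBand(
        covariate=covariate, mean=mean, lower=lo, upper=hi,
        level=level, param_index=param_index,
    )


def interpolate_group_spectrum(
    group: GroupPosterior,
    spec: ModelSpec,
    grid: FrequencyGrid,
    covariate: np.ndarray,
    regressor: int = 1,
    condition: int | None = None,
) -> np.ndarray:
    """Predicted spectra over a covariate range from the group coefficients.

    Returns an array of shape ``(len(covariate), len(grid))``.  Values
    outside the design's covariate support raise a warning, not an error.
    """
    p, R = group.beta_mean.shape
    if R < 2:
        raise ValidationError("interpolation requires an intercept + covariate design")
    covariate = np.asarray(covariate, dtype=float).ravel()
    off = group.design.offsets[regressor] if group.design is not None else 0.0
    if group.design is not None:
        support = group.design.X2[:, regressor] + off
        if covariate.min() < support.min() - 1e-12 or covariate.max() > support.max() + 1e-12:
            warnings.warn("covariate values fall outside the design support", stacklevel=2)
    out = np.empty((covariate.size, len(grid)))
    for i, x in enumerate(covariate):
        theta = group.beta_mean[:, 0] + group.beta_mean[:, regressor] * (x - off)
        if spec.condition_design is not None and condition is not None:
            theta = mdl.condition_expand(theta, spec.condition_design, condition)
        nat = mdl.apply_links(theta, spec.bands)
        S = mdl.evaluate_spectrum(nat, grid, spec.domain)
        out[i] = mdl.apply_filters(S, spec.filters, grid, spec.filter_mode)
    return out
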