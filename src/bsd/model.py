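"""Parametric spectral forward model.

A spectrum is modelled as a power-law aperiodic component plus one
band-limited Gaussian peak per frequency band,

    S(f) = gamma * f**alpha + sum_i h_i * exp(-((f - m_i) / s_i)**2 / 2)

evaluated either on the amplitude scale or with the aperiodic term
replaced by its logarithm (``domain="log"``).  Constrained natural-scale
parameters (gamma, alpha, h, m, s) are obtained from an unconstrained
Gaussian-distributed vector through link functions; the peak frequency
is softly clipped inside its band by a logistic sigmoid.

Unconstrained parameter layout (length ``2 + 3 * n_bands``)::

    [theta_gamma, theta_alpha, (theta_h, theta_m, theta_s) per band]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _signal

from .exceptions import DimensionError, ValidationError

__all__ = [
    "FrequencyGrid",
    "Band",
    "ModelSpec",
    "NaturalParams",
    "PriorSpec",
    "FilterSpec",
    "ConditionDesign",
    "NoiseModel",
    "softclip_sigmoid",
    "apply_links",
    "evaluate_spectrum",
    "apply_filters",
    "condition_expand",
    "baseline_delta_design",
    "noise_covariance",
    "se_correlation",
    "default_priors",
    "scale_spectrum",
    "TARGET_VARIANCE",
    "IDX_GAMMA",
    "IDX_ALPHA",
    "band_slice",
]

#: total signal variance that spectra are rescaled to before fitting
TARGET_VARIANCE = 8.0

# argument clip for exp/sigmoid so arbitrary finite inputs stay finite
_CLIP = 300.0
_SIG_EPS = 1e-12

IDX_GAMMA = 0
IDX_ALPHA = 1


def band_slice(i: int) -> slice:
    """Slice of the raw parameter vector holding (theta_h, theta_m, theta_s) of band ``i``."""
    return slice(2 + 3 * i, 5 + 3 * i)


def softclip_sigmoid(x):
    """Symmetric sigmoid mapping R -> (0, 1) with sigma(0) = 1/2.

    Used to softly clip peak frequencies between their band limits.
    Equivalent to ``(1 + tanh(x / 2)) / 2``.
    """
    x = np.clip(x, -_CLIP, _CLIP)
    s = 1.0 / (1.0 + np.exp(-x))
    return np.clip(s, _SIG_EPS, 1.0 - _SIG_EPS)


def _safe_exp(x):
    return np.exp(np.clip(x, -_CLIP, _CLIP))


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies (Hz)."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or f.size < 2:
            raise ValidationError("frequency grid must be a 1-D array of length >= 2")
        if np.any(f <= 0):
            raise ValidationError("all frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.freqs.size

    @property
    def df(self) -> float:
        """Representative frequency step (median spacing)."""
        return float(np.median(np.diff(self.freqs)))

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "FrequencyGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))


@dataclass(frozen=True)
class Band:
    """A frequency band [lower, upper] hosting at most one peak."""

    name: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValidationError(
                f"band {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, f) -> np.ndarray:
        return (np.asarray(f) >= self.lower) & (np.asarray(f) <= self.upper)


def _check_disjoint(bands: Sequence[Band]) -> None:
    ivals = sorted((b.lower, b.upper, b.name) for b in bands)
    for (l0, u0, n0), (l1, u1, n1) in zip(ivals, ivals[1:]):
        if l1 < u0:
            raise ValidationError(f"bands {n0!r} and {n1!r} overlap")


@dataclass
class FilterSpec:
    """Magnitude response of one filter applied to the data.

    ``kind`` is one of ``highpass_butter``, ``lowpass_butter`` (analog
    Butterworth magnitude) or ``tabulated`` (per-frequency magnitudes,
    linearly interpolated; the table must cover the model grid).
    """

    kind: str
    order: int | None = None
    cutoff: float | None = None
    freqs: np.ndarray | None = None
    magnitude: np.ndarray | None = None

    def __post_init__(self):
        if self.kind in ("highpass_butter", "lowpass_butter"):
            if self.order is None or self.cutoff is None:
                raise ValidationError(f"{self.kind} filter requires order and cutoff")
            if self.order < 1 or self.cutoff <= 0:
                raise ValidationError("filter order must be >=1 and cutoff > 0")
        elif self.kind == "tabulated":
            if self.freqs is None or self.magnitude is None:
                raise ValidationError("tabulated filter requires freqs and magnitude")
            self.freqs = np.asarray(self.freqs, dtype=float)
            self.magnitude = np.asarray(self.magnitude, dtype=float)
            if self.freqs.shape != self.magnitude.shape:
                raise DimensionError("filter table freqs/magnitude length mismatch")
            if np.any(self.magnitude < 0) or np.any(self.magnitude > 1 + 1e-6):
                raise ValidationError("filter magnitudes must lie in [0, 1]")
        else:
            raise ValidationError(f"unknown filter kind {self.kind!r}")

    def response(self, grid: FrequencyGrid) -> np.ndarray:
        """Magnitude |H(f)| evaluated on the grid."""
        f = grid.freqs
        if self.kind == "tabulated":
            if f.min() < self.freqs.min() - 1e-12 or f.max() > self.freqs.max() + 1e-12:
                raise ValidationError(
                    "tabulated filter does not cover the model frequency grid "
                    f"([{self.freqs.min()}, {self.freqs.max()}] vs [{f.min()}, {f.max()}])"
                )
            return np.interp(f, self.freqs, self.magnitude)
        btype = "highpass" if self.kind == "highpass_butter" else "lowpass"
        b, a = _signal.butter(self.order, 2 * np.pi * self.cutoff, btype=btype, analog=True)
        _, h = _signal.freqs(b, a, worN=2 * np.pi * f)
        return np.abs(h)


@dataclass
class ConditionDesign:
    """Per-condition linear maps from the full parameter vector.

    ``matrices[c]`` maps the full unconstrained vector to the effective
    unconstrained parameters of condition ``c`` (links applied after).
    """

    matrices: list[np.ndarray]

    def __post_init__(self):
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if not self.matrices:
            raise ValidationError("condition design needs at least one condition")
        shape = self.matrices[0].shape
        for m in self.matrices:
            if m.ndim != 2 or m.shape != shape:
                raise DimensionError("all condition design matrices must share one shape")

    @property
    def n_conditions(self) -> int:
        return len(self.matrices)

    @property
    def n_full(self) -> int:
        return self.matrices[0].shape[1]

    @property
    def n_per_condition(self) -> int:
        return self.matrices[0].shape[0]


def baseline_delta_design(p: int, n_conditions: int) -> ConditionDesign:
    """Baseline/delta condition encoding.

    Condition 1 is the baseline ``[I 0 ... 0]``; condition c adds its own
    delta block on the unconstrained scale: ``[I 0 .. I .. 0]``.
    """
    if n_conditions < 1:
        raise ValidationError("n_conditions must be >= 1")
    eye = np.eye(p)
    mats = []
    for c in range(n_conditions):
        X = np.zeros((p, p * n_conditions))
        X[:, :p] = eye
        if c > 0:
            X[:, c * p:(c + 1) * p] = eye
        mats.append(X)
    return ConditionDesign(mats)


@dataclass
class ModelSpec:
    """Declarative description of one spectral model."""

    bands: list[Band] = field(default_factory=list)
    domain: str = "amplitude"
    filters: list[FilterSpec] = field(default_factory=list)
    condition_design: ConditionDesign | None = None
    filter_mode: str = "product"

    def __post_init__(self):
        if self.domain not in ("amplitude", "log"):
            raise ValidationError(f"domain must be 'amplitude' or 'log', got {self.domain!r}")
        if self.filter_mode not in ("product", "sum"):
            raise ValidationError("filter_mode must be 'product' or 'sum'")
        _check_disjoint(self.bands)
        if self.condition_design is not None:
            if self.condition_design.n_per_condition != self.n_params:
                raise DimensionError(
                    "condition design rows must equal the per-condition parameter count"
                )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_params(self) -> int:
        """Per-condition unconstrained parameter count (2 + 3 per band)."""
        return 2 + 3 * self.n_bands

    @property
    def n_params_full(self) -> int:
        """Full parameter count including condition deltas."""
        if self.condition_design is not None:
            return self.condition_design.n_full
        return self.n_params


@dataclass
class NaturalParams:
    """Link-mapped natural-scale parameters."""

    gamma: float
    alpha: float
    h: np.ndarray
    m: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if not (self.h.shape == self.m.shape == self.s.shape):
            raise DimensionError("h, m, s must have identical lengths")


@dataclass
class PriorSpec:
    """Gaussian prior over the unconstrained parameters and the noise log-precision."""

    mean: np.ndarray
    cov: np.ndarray
    hyper_mean: float = 0.0
    hyper_var: float = 1.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        p = self.mean.size
        if self.cov.shape != (p, p):
            raise DimensionError("prior covariance shape must match prior mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValidationError("prior covariance must be symmetric")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as e:
            raise ValidationError("prior covariance must be positive definite") from e
        if self.hyper_var < 0:
            raise ValidationError("hyperprior variance must be >= 0")

    @property
    def n_params(self) -> int:
        return self.mean.size


@dataclass
class NoiseModel:
    """Observation-noise covariance ``C = exp(-log_precision) * R``."""

    correlation: np.ndarray
    log_precision: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.correlation, dtype=float)
        self.correlation = R
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise DimensionError("correlation matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValidationError("correlation matrix must be positive semi-definite")


def noise_covariance(noise: NoiseModel) -> np.ndarray:
    """Covariance ``C = exp(-lambda) * R``."""
    return np.exp(-noise.log_precision) * noise.correlation


def se_correlation(grid: FrequencyGrid, length_scale: float) -> np.ndarray:
    """Squared-exponential frequency correlation with the given length scale (Hz)."""
    if length_scale <= 0:
        raise ValidationError("length scale must be > 0")
    d = grid.freqs[:, None] - grid.freqs[None, :]
    return np.exp(-0.5 * (d / length_scale) ** 2)


def apply_links(raw, bands: Sequence[Band]) -> NaturalParams:
    """Map the unconstrained parameter vector to natural-scale parameters.

    gamma = exp(theta_gamma), alpha = -exp(theta_alpha), h_i = exp(theta_hi),
    s_i = exp(theta_si), m_i = L_i + sigmoid(theta_mi) * (U_i - L_i).
    """
    raw = np.asarray(raw, dtype=float).ravel()
    n_bands = len(bands)
    if raw.size != 2 + 3 * n_bands:
        raise DimensionError(
            f"raw parameter vector has length {raw.size}, expected {2 + 3 * n_bands} "
            f"for {n_bands} band(s)"
        )
    gamma = float(_safe_exp(raw[IDX_GAMMA]))
    alpha = float(-_safe_exp(raw[IDX_ALPHA]))
    h = np.empty(n_bands)
    m = np.empty(n_bands)
    s = np.empty(n_bands)
    for i, band in enumerate(bands):
        th, tm, ts = raw[band_slice(i)]
        h[i] = _safe_exp(th)
        m[i] = band.lower + softclip_sigmoid(tm) * band.width
        s[i] = _safe_exp(ts)
    return NaturalParams(gamma=gamma, alpha=alpha, h=h, m=m, s=s)


def evaluate_spectrum(nat: NaturalParams, grid: FrequencyGrid, domain: str = "amplitude") -> np.ndarray:
    """Noise-free model spectrum on the grid.

    Amplitude domain: ``gamma * f**alpha + sum of Gaussian peaks``.
    Log domain: the aperiodic term is replaced by its logarithm; the
    peaks remain additive.
    """
    f = grid.freqs
    aperiodic = nat.gamma * np.exp(nat.alpha * np.log(f))
    peaks = np.zeros_like(f)
    for h, m, s in zip(nat.h, nat.m, nat.s):
        z = (f - m) / s
        peaks += h * np.exp(-0.5 * z * z)
    if domain == "log":
        return np.log(aperiodic) + peaks
    if domain != "amplitude":
        raise ValidationError(f"unknown domain {domain!r}")
    return aperiodic + peaks


def combined_filter_response(
    filters: Sequence[FilterSpec], grid: FrequencyGrid, mode: str = "product"
) -> np.ndarray | None:
    """Combined filter magnitude on the grid, or None for an empty list.

    Filters cascade multiplicatively by default; ``mode="sum"`` adds the
    individual magnitudes instead.
    """
    if not filters:
        return None
    resps = [flt.response(grid) for flt in filters]
    if mode == "sum":
        return np.sum(resps, axis=0)
    out = resps[0].copy()
    for r in resps[1:]:
        out *= r
    return out


def apply_filters(
    S, filters: Sequence[FilterSpec], grid: FrequencyGrid, mode: str = "product"
) -> np.ndarray:
    """Apply the combined filter response to model amplitudes."""
    S = np.asarray(S, dtype=float)
    mult = combined_filter_response(filters, grid, mode)
    if mult is None:
        return S.copy()
    return mult * S


def condition_expand(raw, design: ConditionDesign, c: int) -> np.ndarray:
    """Effective per-condition unconstrained parameters ``X_c @ raw``."""
    raw = np.asarray(raw, dtype=float).ravel()
    if not 0 <= c < design.n_conditions:
        raise ValidationError(f"condition index {c} out of range (n={design.n_conditions})")
    X = design.matrices[c]
    if X.shape[1] != raw.size:
        raise DimensionError(
            f"design expects a full vector of length {X.shape[1]}, got {raw.size}"
        )
    return X @ raw


# Table of default prior variances on the unconstrained scale: 3 for the
# aperiodic amplitude and exponent, 2 for each peak's height, frequency
# and width parameter.  Interpreted as variances.
_VAR_APERIODIC = 3.0
_VAR_PEAK = 2.0


def default_priors(spec: ModelSpec, hyper_mean: float = 0.0, hyper_var: float = 1.0) -> PriorSpec:
    """Default zero-mean diagonal priors for a model specification.

    Covers the per-condition parameters; when a condition design is
    present, delta blocks get the same variances as their base block.
    """
    base = [_VAR_APERIODIC, _VAR_APERIODIC] + [_VAR_PEAK] * (3 * spec.n_bands)
    p_full = spec.n_params_full
    if p_full % spec.n_params != 0:
        variances = base * (p_full // len(base)) + base[: p_full % len(base)]
    else:
        variances = base * (p_full // spec.n_params)
    variances = np.asarray(variances[:p_full], dtype=float)
    return PriorSpec(
        mean=np.zeros(p_full),
        cov=np.diag(variances),
        hyper_mean=hyper_mean,
        hyper_var=hyper_var,
    )


def scale_spectrum(
    spectrum, grid: FrequencyGrid, target_variance: float = TARGET_VARIANCE
) -> tuple[np.ndarray, float]:
    """Rescale amplitudes so the implied total signal variance equals the target.

    The implied variance is ``sum(S**2) * df`` (power integrated over the
    grid).  Returns the scaled spectrum and the multiplicative factor.
    """
    S = np.asarray(spectrum, dtype=float)
    implied = float(np.sum(S * S) * grid.df)
    if implied <= 0:
        raise ValidationError("cannot scale an all-zero spectrum")
    factor = float(np.sqrt(target_variance / implied))
    return S * factor, factor
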