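"""Synthetic spectra generators used as a download-free test harness.

Two designs are provided:

* a two-condition (rest/task) group study of 32 subjects whose spectral
  parameters depend linearly on a continuous covariate, with a large
  alpha-band peak and a smaller beta-band peak that the task condition
  attenuates; and
* a single-peak detection benchmark: batches of random spectra, half
  with a peak of fixed SNR placed in a chosen band and half aperiodic
  only, used for ROC evaluation of detection criteria.

All randomness is routed through a seeded generator; datasets are
bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import model as mdl
from .exceptions import ValidationError
from .model import Band, FrequencyGrid, NaturalParams

__all__ = [
    "GroupSimConfig",
    "BenchmarkConfig",
    "GroupDataset",
    "LabeledSpectra",
    "simulate_group",
    "simulate_benchmark",
    "nominal_group_params",
    "sample_group_params",
]

CONDITIONS = ("rest", "task")


@dataclass
class GroupSimConfig:
    """Generative constants for the two-condition group simulation.

    The covariate is uniform on [0, 1] and lowers the alpha peak's
    frequency and height; the task condition attenuates both peak
    heights.  Parameter noise is centred Gaussian on the natural scale
    with sd equal to ``param_noise_frac`` times each parameter's nominal
    value.  All constants are overridable.
    """

    n_subjects: int = 32
    f_lo: float = 1.0
    f_hi: float = 32.0
    f_step: float = 0.5
    alpha_band: tuple = ("alpha", 8.0, 12.0)
    beta_band: tuple = ("beta", 12.0, 30.0)
    # aperiodic component
    aperiodic_amp: float = 1.0
    aperiodic_exp: float = -0.8
    # alpha peak at covariate 0 and its linear covariate effects
    alpha_height: float = 2.2
    alpha_height_slope: float = -0.6
    alpha_freq: float = 11.0
    alpha_freq_slope: float = -2.0
    alpha_width: float = 1.4
    # beta peak (covariate-independent)
    beta_height: float = 0.25
    beta_freq: float = 19.0
    beta_width: float = 2.5
    # multiplicative attenuation of both peak heights in the task condition
    task_attenuation: float = 0.3
    param_noise_frac: float = 0.15
    noise_log_precision: float = 9.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.param_noise_frac < 0:
            raise ValidationError("param_noise_frac must be >= 0")

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.from_range(self.f_lo, self.f_hi, self.f_step)

    @property
    def bands(self) -> list[Band]:
        return [Band(*self.alpha_band), Band(*self.beta_band)]

    @property
    def n_conditions(self) -> int:
        return len(CONDITIONS)


@dataclass
class GroupDataset:
    """Simulated group data: spectra (subjects x conditions x freqs) + truth."""

    spectra: np.ndarray
    covariate: np.ndarray
    true_params: list  # per subject: per condition NaturalParams
    grid: FrequencyGrid
    config: GroupSimConfig

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0] * self.spectra.shape[1]

    def iter_spectra(self):
        """Yield (label, subject_index, condition_index, spectrum)."""
        for k in range(self.spectra.shape[0]):
            for c, cond in enumerate(CONDITIONS):
                yield f"sub{k:02d}_{cond}", k, c, self.spectra[k, c]


def nominal_group_params(cfg: GroupSimConfig, covariate: float, condition: int) -> np.ndarray:
    """Noise-free natural-scale parameter vector [gamma, alpha, h_a, m_a, s_a, h_b, m_b, s_b]."""
    att = cfg.task_attenuation if CONDITIONS[condition] == "task" else 1.0
    return np.array(
        [
            cfg.aperiodic_amp,
            cfg.aperiodic_exp,
            att * (cfg.alpha_height + cfg.alpha_height_slope * covariate),
            cfg.alpha_freq + cfg.alpha_freq_slope * covariate,
            cfg.alpha_width,
            att * cfg.beta_height,
            cfg.beta_freq,
            cfg.beta_width,
        ]
    )


def sample_group_params(
    cfg: GroupSimConfig, covariate: float, condition: int, rng: np.random.Generator
) -> NaturalParams:
    """Nominal parameters perturbed on the natural scale (sd = frac * nominal).

    Positivity is preserved by flooring at a small fraction of the
    nominal magnitude, and peak frequencies are kept inside their band.
    """
    nominal = nominal_group_params(cfg, covariate, condition)
    sd = cfg.param_noise_frac * np.abs(nominal)
    vals = nominal + rng.normal(0.0, 1.0, nominal.size) * sd
    floor = 1e-3 * np.abs(nominal)
    # gamma, heights and widths stay positive; the exponent stays negative
    for i in (0, 2, 4, 5, 7):
        vals[i] = max(vals[i], floor[i])
    vals[1] = min(vals[1], -floor[1])
    bands = cfg.bands
    for i, bidx in ((3, 0), (6, 1)):
        b = bands[bidx]
        pad = 0.02 * b.width
        vals[i] = float(np.clip(vals[i], b.lower + pad, b.upper - pad))
    return NaturalParams(
        gamma=vals[0], alpha=vals[1],
        h=vals[[2, 5]], m=vals[[3, 6]], s=vals[[4, 7]],
    )


def simulate_group(cfg: GroupSimConfig | None = None, seed: int | None = None) -> GroupDataset:
    """Generate the two-condition, covariate-modulated group dataset.

    For each subject: draw the covariate, compute condition-specific
    generative parameters, perturb them with centred Gaussian parameter
    noise, evaluate the spectral model on the grid and add Gaussian
    observation noise.
    """
    cfg = cfg or GroupSimConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    grid = cfg.grid
    n = len(grid)
    noise_sd = np.exp(-cfg.noise_log_precision / 2.0)
    spectra = np.empty((cfg.n_subjects, cfg.n_conditions, n))
    covariate = rng.uniform(0.0, 1.0, cfg.n_subjects)
    truth = []
    for k in range(cfg.n_subjects):
        per_cond = []
        for c in range(cfg.n_conditions):
            nat = sample_group_params(cfg, covariate[k], c, rng)
            S = mdl.evaluate_spectrum(nat, grid, "amplitude")
            spectra[k, c] = S + rng.normal(0.0, noise_sd, n)
            per_cond.append(nat)
        truth.append(per_cond)
    return GroupDataset(
        spectra=spectra, covariate=covariate, true_params=truth, grid=grid, config=cfg
    )


@dataclass
class BenchmarkConfig:
    """Single-peak SNR benchmark configuration.

    Peak heights are set on the amplitude-dB scale relative to the sum of
    the aperiodic level at the peak location and the output-noise sd;
    the output-noise variance is ``exp(-noise_log_precision)`` times the
    squared mean aperiodic level.  Unstated generative ranges: peak
    width uniform in [5%, 25%] of the bandwidth, exponent uniform in
    [-2, -0.5], amplitude log-uniform over one decade.
    """

    band: tuple = ("beta", 12.0, 30.0)
    n_spectra: int = 1024
    f_lo: float = 1.0
    f_hi: float = 64.0
    f_step: float = 0.5
    snr_db: float = 0.0
    noise_log_precision: float = 4.0
    width_frac: tuple = (0.05, 0.25)
    exponent_range: tuple = (-2.0, -0.5)
    amp_range: tuple = (0.5, 5.0)
    seed: int | None = None

    def __post_init__(self):
        if self.n_spectra < 2:
            raise ValidationError("n_spectra must be >= 2")
        b = Band(*self.band)
        if b.lower < self.f_lo or b.upper > self.f_hi:
            raise ValidationError(
                f"band [{b.lower}, {b.upper}] is not contained in the grid "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.from_range(self.f_lo, self.f_hi, self.f_step)

    @property
    def band_obj(self) -> Band:
        return Band(*self.band)


@dataclass
class LabeledSpectra:
    """Benchmark spectra with peak-presence labels and generative truth."""

    spectra: np.ndarray  # (n_spectra, n_freqs)
    labels: np.ndarray  # 1 = peak present
    truth: list
    grid: FrequencyGrid
    config: BenchmarkConfig


def simulate_benchmark(cfg: BenchmarkConfig | None = None, seed: int | None = None) -> LabeledSpectra:
    """Generate a balanced batch of peak / no-peak spectra at fixed SNR."""
    cfg = cfg or BenchmarkConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    grid = cfg.grid
    f = grid.freqs
    band = cfg.band_obj
    n_pos = cfg.n_spectra // 2
    labels = np.zeros(cfg.n_spectra, dtype=int)
    labels[:n_pos] = 1
    amp_factor = 10.0 ** (cfg.snr_db / 20.0)
    spectra = np.empty((cfg.n_spectra, f.size))
    truth = []
    for i in range(cfg.n_spectra):
        alpha = rng.uniform(*cfg.exponent_range)
        gamma = np.exp(rng.uniform(np.log(cfg.amp_range[0]), np.log(cfg.amp_range[1])))
        A = gamma * f ** alpha
        sd = float(np.exp(-cfg.noise_log_precision / 2.0) * A.mean())
        rec = {"gamma": gamma, "alpha": alpha, "noise_sd": sd, "peak": None}
        S = A.copy()
        if labels[i]:
            m = rng.uniform(band.lower, band.upper)
            s = rng.uniform(*cfg.width_frac) * band.width
            a_at_m = float(gamma * m ** alpha)
            h = amp_factor * (a_at_m + sd)
            S = S + h * np.exp(-0.5 * ((f - m) / s) ** 2)
            rec["peak"] = {"h": float(h), "m": float(m), "s": float(s)}
        spectra[i] = S + rng.normal(0.0, sd, f.size)
        truth.append(rec)
    return LabeledSpectra(spectra=spectra, labels=labels, truth=truth, grid=grid, config=cfg)
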