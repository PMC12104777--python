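import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal

from bsd import Band, FrequencyGrid, ModelSpec, NaturalParams, PriorSpec, apply_links
from bsd.exceptions import DimensionError, NumericalError
from bsd.inversion import (
    FitOptions,
    bmr_reduce,
    fit,
    fit_forward,
    free_energy,
    gaussian_kl,
    jacobian,
    spectral_forward,
)
from bsd.model import evaluate_spectrum

from conftest import make_posterior


def linear_problem(seed=0, n=40, p=3, sigma2=0.25):
    """Linear-Gaussian test model with its conjugate closed form."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    theta = rng.normal(size=p)
    y = X @ theta + rng.normal(0, np.sqrt(sigma2), n)
    mu0 = np.zeros(p)
    S0 = np.eye(p) * 2.0
    lam = np.log(1.0 / sigma2)
    P = np.linalg.inv(S0) + np.exp(lam) * X.T @ X
    Sigma = np.linalg.inv(P)
    mu = Sigma @ (np.linalg.inv(S0) @ mu0 + np.exp(lam) * X.T @ y)
    logev = multivariate_normal.logpdf(y, X @ mu0, sigma2 * np.eye(n) + X @ S0 @ X.T)
    priors = PriorSpec(mean=mu0, cov=S0, hyper_mean=lam, hyper_var=1.0)
    return X, y, priors, mu, Sigma, logev


class TestConjugateOracle:
    """fit must reproduce the closed-form Gaussian posterior and evidence."""

    def test_posterior_and_evidence_match_closed_form(self):
        X, y, priors, mu, Sigma, logev = linear_problem()
        opts = FitOptions(update_lambda=False, tol_df=1e-10, max_iter=200)
        post = fit_forward(y, lambda t: (X @ t, X), priors, opts)
        np.testing.assert_allclose(post.mean, mu, rtol=1e-6)
        np.testing.assert_allclose(post.cov, Sigma, rtol=1e-6)
        assert post.free_energy == pytest.approx(logev, rel=1e-6)

    def test_posterior_variance_never_exceeds_prior(self):
        X, y, priors, *_ = linear_problem(seed=3)
        opts = FitOptions(update_lambda=False)
        post = fit_forward(y, lambda t: (X @ t, X), priors, opts)
        assert np.linalg.eigvalsh(post.cov).max() <= np.linalg.eigvalsh(priors.cov).max() + 1e-10

    def test_deterministic(self):
        X, y, priors, *_ = linear_problem(seed=5)
        opts = FitOptions(update_lambda=False)
        p1 = fit_forward(y, lambda t: (X @ t, X), priors, opts)
        p2 = fit_forward(y, lambda t: (X @ t, X), priors, opts)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        assert p1.free_energy == p2.free_energy


class TestFreeEnergy:
    def test_posterior_equals_prior_zero_complexity(self):
        assert gaussian_kl([0.0], [[1.0]], [0.0], [[1.0]]) == 0.0

    def test_scalar_kl_half(self):
        # KL(N(1,1) || N(0,1)) = 0.5
        assert gaussian_kl([1.0], [[1.0]], [0.0], [[1.0]]) == pytest.approx(0.5)

    def test_decomposition_identity_and_nonnegativity(self, grid):
        true = NaturalParams(gamma=1.0, alpha=-1.0, h=[0.8], m=[10.0], s=[1.5])
        y = evaluate_spectrum(true, grid)
        y = y + np.random.default_rng(0).normal(0, 0.02, len(grid))
        post = fit(y, grid, ModelSpec(bands=[Band("alpha", 8, 12)]))
        assert post.complexity_theta >= 0
        assert post.complexity_lambda >= 0
        assert post.free_energy == pytest.approx(
            post.accuracy - post.complexity_theta - post.complexity_lambda
        )

    def test_monotone_trace(self, grid):
        true = NaturalParams(gamma=1.0, alpha=-1.0, h=[0.8], m=[10.0], s=[1.5])
        y = evaluate_spectrum(true, grid)
        y = y + np.random.default_rng(1).normal(0, 0.02, len(grid))
        post = fit(y, grid, ModelSpec(bands=[Band("alpha", 8, 12)]))
        diffs = np.diff(post.trace)
        assert np.all(diffs > 0)  # only accepted (improving) steps are recorded


class TestJacobian:
    def test_aperiodic_amplitude_column(self, grid):
        spec = ModelSpec(bands=[])
        theta = np.array([0.3, -0.2])
        J = jacobian(theta, spec, grid)
        nat = apply_links(theta, [])
        aperiodic = nat.gamma * grid.freqs ** nat.alpha
        np.testing.assert_allclose(J[:, 0], aperiodic)

    def test_height_column_at_mode(self):
        band = Band("alpha", 8, 12)
        spec = ModelSpec(bands=[band])
        theta = np.array([0.0, 0.0, 0.4, 0.0, 0.0])
        nat = apply_links(theta, [band])
        g = FrequencyGrid([9.0, nat.m[0], 11.0])
        J = jacobian(theta, spec, g)
        assert J[1, 2] == pytest.approx(nat.h[0])

    @pytest.mark.parametrize("domain", ["amplitude", "log"])
    def test_matches_finite_differences(self, grid, domain):
        spec = ModelSpec(
            bands=[Band("alpha", 8, 12), Band("beta", 12, 30)], domain=domain
        )
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = rng.normal(0, 0.7, 8)
            Ja = jacobian(theta, spec, grid)
            Jf = jacobian(theta, spec, grid, method="finite_diff")
            np.testing.assert_allclose(Ja, Jf, atol=1e-5 * max(1.0, np.abs(Ja).max()))

    def test_condition_design_stacks(self, grid):
        from bsd.model import baseline_delta_design

        spec = ModelSpec(
            bands=[Band("alpha", 8, 12)],
            condition_design=baseline_delta_design(5, 2),
        )
        fwd = spectral_forward(spec, grid)
        s, J = fwd(np.zeros(10))
        assert s.shape == (2 * len(grid),)
        assert J.shape == (2 * len(grid), 10)


class TestSpectralFit:
    def test_parameter_recovery_high_precision(self, grid):
        true = NaturalParams(gamma=1.0, alpha=-1.0, h=[0.8], m=[10.0], s=[1.5])
        y = evaluate_spectrum(true, grid)
        y = y + np.random.default_rng(2).normal(0, 0.01, len(grid))
        band = Band("alpha", 8, 12)
        spec = ModelSpec(bands=[band])
        post = fit(y, grid, spec)
        assert post.converged
        nat = apply_links(post.mean, [band])
        # delta-method posterior sd on the natural scale
        sd_raw = np.sqrt(np.diag(post.cov))
        truths = [true.gamma, true.alpha, true.h[0], true.m[0], true.s[0]]
        ests = [nat.gamma, nat.alpha, nat.h[0], nat.m[0], nat.s[0]]
        from bsd.model import softclip_sigmoid

        sig = softclip_sigmoid(post.mean[3])
        dlink = [
            nat.gamma,
            abs(nat.alpha),
            nat.h[0],
            sig * (1 - sig) * band.width,
            nat.s[0],
        ]
        for t, e, d, sr in zip(truths, ests, dlink, sd_raw):
            assert abs(e - t) <= 3 * d * sr + 1e-9

    def test_conservatism_on_pure_noise(self, grid):
        rng = np.random.default_rng(2)
        nat = NaturalParams(gamma=1.0, alpha=-1.0, h=[], m=[], s=[])
        y = evaluate_spectrum(nat, grid) + rng.normal(0, 0.01, len(grid))
        f_peak = fit(y, grid, ModelSpec(bands=[Band("alpha", 8, 12)]))
        f_null = fit(y, grid, ModelSpec(bands=[]))
        assert f_peak.free_energy < f_null.free_energy
        # fitted peak height concentrates near small values
        nat_fit = apply_links(f_peak.mean, [Band("alpha", 8, 12)])
        assert nat_fit.h[0] < 0.1

    def test_grid_mismatch(self, grid):
        with pytest.raises(DimensionError):
            fit(np.ones(10), grid, ModelSpec(bands=[]))

    def test_finite_diff_option_agrees(self, grid):
        true = NaturalParams(gamma=1.0, alpha=-1.0, h=[0.8], m=[10.0], s=[1.5])
        y = evaluate_spectrum(true, grid)
        y = y + np.random.default_rng(4).normal(0, 0.02, len(grid))
        spec = ModelSpec(bands=[Band("alpha", 8, 12)])
        fa = fit(y, grid, spec, opts=FitOptions(jacobian="analytic"))
        ff = fit(y, grid, spec, opts=FitOptions(jacobian="finite_diff"))
        assert fa.free_energy == pytest.approx(ff.free_energy, abs=0.01)

    def test_two_condition_fit(self, grid):
        from bsd.model import baseline_delta_design, default_priors

        band = Band("alpha", 8, 12)
        spec = ModelSpec(bands=[band], condition_design=baseline_delta_design(5, 2))
        rng = np.random.default_rng(8)
        base = np.array([0.0, 0.0, 0.5, 0.0, 0.3])
        delta = np.array([0.0, 0.0, -1.0, 0.0, 0.0])  # task attenuates the peak
        y = np.stack(
            [
                evaluate_spectrum(apply_links(base, [band]), grid),
                evaluate_spectrum(apply_links(base + delta, [band]), grid),
            ]
        )
        y = y + rng.normal(0, 0.01, y.shape)
        post = fit(y, grid, spec)
        assert post.converged
        # recovered height delta close to -1 on the unconstrained scale
        assert post.mean[7] == pytest.approx(-1.0, abs=0.3)


class TestBMR:
    def test_identity_reduction(self):
        prior = PriorSpec(mean=np.zeros(2), cov=np.eye(2))
        post = make_posterior([0.4, -0.2], np.eye(2) * 0.3, F=-12.0)
        red, dF = bmr_reduce(post, prior, prior)
        assert dF == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(red.mean, post.mean)

    def test_matches_1d_quadrature(self):
        prior = PriorSpec(mean=[0.0], cov=[[1.0]])
        reduced = PriorSpec(mean=[0.0], cov=[[0.25]])
        post = make_posterior([0.5], [[0.5]])
        red, dF = bmr_reduce(post, prior, reduced)

        def npdf(x, m, v):
            return np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)

        f = lambda x: npdf(x, 0.5, 0.5) * npdf(x, 0.0, 0.25) / npdf(x, 0.0, 1.0)
        Z, _ = integrate.quad(f, -30, 30)
        m1, _ = integrate.quad(lambda x: x * f(x) / Z, -30, 30)
        v1, _ = integrate.quad(lambda x: (x - m1) ** 2 * f(x) / Z, -30, 30)
        assert dF == pytest.approx(np.log(Z), abs=1e-8)
        assert red.mean[0] == pytest.approx(m1, abs=1e-8)
        assert red.cov[0, 0] == pytest.approx(v1, abs=1e-8)

    def test_reduction_matches_direct_refit(self):
        # shrinking one prior variance to ~0 removes that parameter
        X, y, priors, *_ = linear_problem(seed=9, n=30, p=3)
        opts = FitOptions(update_lambda=False, tol_df=1e-10, max_iter=300)
        full = fit_forward(y, lambda t: (X @ t, X), priors, opts)
        cov_r = priors.cov.copy()
        cov_r[2, 2] = 1e-8
        reduced_prior = PriorSpec(
            mean=priors.mean, cov=cov_r,
            hyper_mean=priors.hyper_mean, hyper_var=priors.hyper_var,
        )
        red, dF = bmr_reduce(full, priors, reduced_prior)
        direct = fit_forward(y, lambda t: (X @ t, X), reduced_prior, opts)
        assert full.free_energy + dF == pytest.approx(direct.free_energy, abs=0.5)

    def test_invalid_reduction_raises(self):
        prior = PriorSpec(mean=[0.0], cov=[[1.0]])
        wider = PriorSpec(mean=[0.0], cov=[[100.0]])
        post = make_posterior([0.0], [[2.0]])  # less precise than its prior
        with pytest.raises(NumericalError):
            bmr_reduce(post, prior, wider)

    def test_dimension_mismatch(self):
        prior = PriorSpec(mean=np.zeros(2), cov=np.eye(2))
        reduced = PriorSpec(mean=[0.0], cov=[[1.0]])
        post = make_posterior([0.0, 0.0], np.eye(2))
        with pytest.raises(DimensionError):
            bmr_reduce(post, prior, reduced)
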