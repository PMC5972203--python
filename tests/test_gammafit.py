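import numpy as np
import pytest
from scipy.integrate import quad

from chemotrack.diffusion import build_histogram
from chemotrack.gammafit import (
    GammaComponent,
    GammaMixtureFit,
    MixtureConstraints,
    bootstrap_errors,
    fit_mixture,
    fit_single_gamma,
    gamma_pdf,
    iterative_refine,
    select_model,
)

DT = 6.5e-4


def test_gamma_pdf_exponential_special_case():
    """N=1 reduces to the exponential: density 1/D at the origin."""
    assert gamma_pdf(np.array([1e-12]), 2.0, 1.0)[0] == pytest.approx(0.5, rel=1e-6)
    x = np.array([1.0, 3.0])
    assert gamma_pdf(x, 2.0, 1.0) == pytest.approx(0.5 * np.exp(-x / 2.0))


def test_gamma_pdf_normalization_non_integer_n():
    val, _ = quad(lambda x: gamma_pdf(np.array([x]), 6.2, 2.0)[0], 0, np.inf)
    assert val == pytest.approx(1.0, abs=1e-8)
    val, _ = quad(lambda x: gamma_pdf(np.array([x]), 1.72, 2.24)[0], 0, np.inf)
    assert val == pytest.approx(1.0, abs=1e-8)


def test_gamma_pdf_moments_monte_carlo():
    """Draws from the matching numpy gamma have mean D and variance D²/N."""
    d, n = 8.4, 2.0
    rng = np.random.default_rng(0)
    draws = rng.gamma(n, d / n, size=10**6)
    se = d / np.sqrt(n * draws.size)
    assert abs(draws.mean() - d) < 3.0 * se
    assert draws.var() == pytest.approx(d**2 / n, rel=0.01)


def test_gamma_pdf_rejects_bad_parameters():
    with pytest.raises(ValueError):
        gamma_pdf(np.array([1.0]), -1.0, 2.0)
    with pytest.raises(ValueError):
        gamma_pdf(np.array([1.0]), 1.0, 0.0)


def test_single_gamma_self_consistency():
    """Fit to 1e5 gamma(D=5, N=2) draws recovers D within 2%."""
    rng = np.random.default_rng(1)
    vals = rng.gamma(2.0, 5.0 / 2.0, size=10**5)
    hist = build_histogram(vals, 40.0, DT)
    fit = fit_single_gamma(hist, n_free=True, estimates=vals)
    c = fit.components[0]
    assert c.d == pytest.approx(5.0, rel=0.02)
    assert c.n == pytest.approx(2.0, rel=0.15)
    assert fit.weights_sum == pytest.approx(1.0, abs=1e-6)


def test_single_gamma_histogram_path():
    rng = np.random.default_rng(2)
    vals = rng.gamma(2.0, 5.0 / 2.0, size=3 * 10**4)
    hist = build_histogram(vals, 40.0, DT)
    fit = fit_single_gamma(hist, n_free=True)
    assert fit.components[0].d == pytest.approx(5.0, rel=0.05)


def test_degenerate_histogram_raises():
    hist = build_histogram(np.zeros(100), 40.0, DT)
    with pytest.raises(ValueError):
        fit_single_gamma(hist, n_free=True)


def test_mixture_weight_zero_equals_single():
    """A mixture whose second weight is forced to ~0 matches the single fit."""
    rng = np.random.default_rng(3)
    vals = rng.gamma(2.0, 5.0 / 2.0, size=2 * 10**4)
    hist = build_histogram(vals, 40.0, DT)
    single = fit_single_gamma(hist, n_free=True)
    c = single.components[0]
    forced = GammaMixtureFit([
        GammaComponent(c.d, c.n, 1.0),
        GammaComponent(50.0, 2.0, 0.0),
    ])
    x = hist.centers
    assert np.allclose(forced.pdf(x), single.pdf(x), atol=1e-9)


def test_known_mixture_recovery():
    """Constrained scheme on gamma(2,2)+gamma(9,2) halves: both D within 10%."""
    rng = np.random.default_rng(4)
    vals = np.concatenate([
        rng.gamma(2.0, 2.0 / 2.0, size=5000),
        rng.gamma(2.0, 9.0 / 2.0, size=5000),
    ])
    # 20 nm precision: bins fine enough to resolve the slow component
    hist = build_histogram(vals, 20.0, DT)
    cons = MixtureConstraints(immobile_d_max=3.0, immobile_n_max=4.0,
                              mobile_n_fixed=2.0)
    fit = fit_mixture(hist, 2, cons)
    d_slow, d_fast = fit.components[0].d, fit.components[1].d
    assert d_slow == pytest.approx(2.0, rel=0.10)
    assert d_fast == pytest.approx(9.0, rel=0.10)
    assert fit.weights_sum == pytest.approx(1.0, abs=1e-6)


def test_select_model_prefers_true_component_count():
    rng = np.random.default_rng(5)
    one = rng.gamma(2.0, 5.0 / 2.0, size=2 * 10**4)
    two = np.concatenate([
        rng.gamma(2.0, 1.6 / 2.0, size=10**4),
        rng.gamma(2.0, 10.0 / 2.0, size=10**4),
    ])
    for vals, expected in ((one, 1), (two, 2)):
        hist = build_histogram(vals, 40.0, DT)
        cons = MixtureConstraints(immobile_d_max=hist.bin_width * 2,
                                  immobile_n_max=4.0, mobile_n_fixed=None)
        fits = {1: fit_mixture(hist, 1, cons)}
        fits[2] = fit_mixture(hist, 2, cons)
        assert select_model(fits) == expected


def test_reduced_chi2_never_prefers_worse_nested_model():
    rng = np.random.default_rng(6)
    vals = rng.gamma(2.0, 5.0 / 2.0, size=10**4)
    hist = build_histogram(vals, 40.0, DT)
    fit1 = fit_single_gamma(hist, n_free=True)
    # same parameter count, strictly larger chi2 -> never selected
    worse = GammaMixtureFit(
        [GammaComponent(fit1.components[0].d * 2.0, fit1.components[0].n, 1.0)]
    )
    worse.chi2 = fit1.chi2 * 10
    worse.reduced_chi2 = fit1.reduced_chi2 * 10
    assert select_model({1: fit1, 2: worse}) == 1


def test_bootstrap_constant_fit_gives_zero_sd():
    vals = np.linspace(1, 10, 100)

    def constant_fit(sub):
        return GammaMixtureFit([GammaComponent(5.0, 2.0, 1.0)])

    errs = bootstrap_errors(vals, constant_fit, seed=0)
    assert all(v == 0.0 for v in errs.values())


def test_bootstrap_sd_shrinks_with_sample_size():
    """Subsampling SD scales roughly as 1/sqrt(n) (factor sqrt(10) per decade)."""
    rng = np.random.default_rng(7)

    def proc(sub):
        h = build_histogram(sub, 40.0, DT)
        return fit_single_gamma(h, n_free=True, estimates=sub)

    sds = {}
    for n in (10**3, 10**4):
        vals = rng.gamma(2.0, 5.0 / 2.0, size=n)
        sds[n] = bootstrap_errors(vals, proc, repeats=10, seed=1)["d1"]
    ratio = sds[10**3] / sds[10**4]
    assert np.sqrt(10) / 1.5 < ratio < np.sqrt(10) * 1.5


def test_bootstrap_rejects_tiny_datasets():
    with pytest.raises(ValueError):
        bootstrap_errors(np.ones(5), lambda s: None)


def test_error_report_formatting():
    fit = GammaMixtureFit([GammaComponent(0.3, 0.5, 0.5),
                           GammaComponent(8.93, 2.0, 0.5)])
    fit.errors = {"d1": 0.05, "d2": 0.42}
    assert "8.9 ± 0.4" in fit.summary()


def _gt_histogram(components, n_per, rng):
    """Ground-truth-level pipeline hook: sample the estimator distribution."""
    dt = DT
    vals = []
    for c in components:
        d = max(c.d, 1e-3)
        steps = rng.normal(0, np.sqrt(2 * d * dt), size=(n_per, 4, 2))
        pos = np.concatenate([np.zeros((n_per, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
        msd = np.stack([
            np.mean(np.sum((pos[:, k:] - pos[:, :-k]) ** 2, axis=2), axis=1)
            for k in range(1, 5)
        ], axis=1)
        vals.append(np.mean(msd / (4 * np.arange(1, 5) * dt), axis=1))
    vals = np.concatenate(vals)
    return vals, build_histogram(vals, 20.0, dt)


def test_iterative_refine_recovers_mixture_and_converges():
    rng = np.random.default_rng(8)
    est, hist = _gt_histogram(
        [GammaComponent(0.05, 1.0, 0.5), GammaComponent(9.0, 2.0, 0.5)], 2000, rng
    )

    def hook(components):
        return _gt_histogram(components, 2000, rng)

    fit = iterative_refine(est, hist, hook, max_iter=4)
    assert fit.converged
    mobile = fit.components[-1]
    assert mobile.d == pytest.approx(9.0, rel=0.10)
    assert mobile.n == 2.0
    assert fit.components[0].n <= 1.0
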