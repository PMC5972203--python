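"""Gamma-mixture modelling of microscopic diffusion-coefficient distributions.

The sampling distribution of an MSD-based diffusion estimate from N
independent steps is a gamma distribution with mean D (the true coefficient)
and shape N:

    F(x; D, N) = (N/D)^N x^(N-1) exp(-N x / D) / Γ(N)

With overlapping short-track MSD windows the effective N is near two, and a
population mixing immobile and mobile molecules is modelled as a weighted sum
of such components.  Fitting is least squares of the model density against a
boundary-corrected kernel density estimate of the per-track coefficients
(Gaussian kernel, Silverman bandwidth, reflected at x=0), with goodness of
fit (χ², reduced χ², R²) evaluated on the localization-precision-width
histogram using Poisson count weights.  Model order is chosen by reduced χ²,
and parameter errors come from repeated-subsampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .diffusion import DiffusionHistogram

__all__ = [
    "GammaComponent",
    "GammaMixtureFit",
    "MixtureConstraints",
    "gamma_pdf",
    "reflected_kde",
    "fit_single_gamma",
    "fit_mixture",
    "select_model",
    "iterative_refine",
    "bootstrap_errors",
]


def gamma_pdf(x, d, n):
    """Gamma density with mean d and shape n ((N-1)! generalized to Γ(N)).

    Normalized on x >= 0; mean d, variance d²/n.  Vectorized in x; zero for
    x <= 0.
    """
    if d <= 0 or n <= 0:
        raise ValueError("d and n must be positive")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = np.exp(
        n * np.log(n / d) + (n - 1.0) * np.log(x[pos]) - n * x[pos] / d - gammaln(n)
    )
    return out


@dataclass
class GammaComponent:
    d: float  # µm²/s
    n: float  # effective independent steps
    weight: float


@dataclass
class GammaMixtureFit:
    components: list[GammaComponent]
    chi2: float = np.nan
    reduced_chi2: float = np.nan
    r2: float = np.nan
    errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.d)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for c in self.components:
            out += c.weight * gamma_pdf(x, c.d, c.n)
        return out

    @property
    def weights_sum(self) -> float:
        return sum(c.weight for c in self.components)

    def summary(self) -> str:
        parts = []
        for c in self.components:
            err = self.errors.get(f"d{len(parts) + 1}")
            if err is not None:
                parts.append(f"D = {c.d:.1f} ± {err:.1f} µm²/s (N={c.n:.2f}, w={c.weight:.2f})")
            else:
                parts.append(f"D = {c.d:.2f} µm²/s (N={c.n:.2f}, w={c.weight:.2f})")
        return "; ".join(parts)


def reflected_kde(values: np.ndarray, grid_points: int = 300, top_quantile: float = 99.5):
    """Gaussian KDE (robust Silverman bandwidth) reflected at x=0.

    Returns (grid, density, bandwidth) with the grid on (0, q_top] of the
    data.  Reflection corrects the boundary bias a plain kernel estimate
    suffers for densities supported on [0, inf); mass smeared below zero
    folds onto its mirror image, preserving the total on integration over
    x>0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for a KDE")
    refl = np.concatenate([v, -v])
    # robust Silverman rule: heavy-tailed estimate distributions inflate the
    # plain SD-based bandwidth, over-smoothing the peak
    spread = min(refl.std(), (np.percentile(refl, 75) - np.percentile(refl, 25)) / 1.349)
    spread = spread if spread > 0 else refl.std()
    if spread == 0:
        raise ValueError("degenerate (constant) sample")
    kde = gaussian_kde(refl, bw_method=0.9 * spread * refl.size ** (-0.2) / refl.std())
    bw = float(np.sqrt(kde.covariance[0, 0]))
    top = float(np.percentile(v, top_quantile))
    top = max(top, float(np.median(v)) + 1e-6)
    grid = np.linspace(top / grid_points, top, grid_points)
    return grid, 2.0 * kde(grid), bw


class _KdeFitTarget:
    """Reflected-KDE curve plus the matching kernel-convolved model.

    Fitting a sharp parametric density directly to a kernel density estimate
    is biased by the kernel's own broadening; here the candidate gamma
    density is convolved with the same Gaussian kernel and reflected at zero
    before comparison, so the data-side and model-side smoothing cancel.
    Weights follow the KDE's sampling error (proportional to sqrt(density),
    floored at 1/1000 of the peak).
    """

    def __init__(self, values: np.ndarray):
        self.grid, self.density, self.bw = reflected_kde(values)
        top = self.grid[-1]
        self.support = np.linspace(0.0, top + 6.0 * self.bw, 900)
        dt = self.support[1] - self.support[0]
        diff = self.grid[:, None] - self.support[None, :]
        summ = self.grid[:, None] + self.support[None, :]
        norm = dt / (math.sqrt(2.0 * math.pi) * self.bw)
        self.kernel = (
            np.exp(-(diff**2) / (2.0 * self.bw**2))
            + np.exp(-(summ**2) / (2.0 * self.bw**2))
        ) * norm
        self.sigma = np.sqrt(np.maximum(self.density, self.density.max() * 1e-3))

    def model(self, pdf_on_support: np.ndarray) -> np.ndarray:
        return self.kernel @ pdf_on_support


def _hist_gof(hist: DiffusionHistogram, pdf, n_params: int):
    """χ², reduced χ² and R² of a fitted density on the histogram bins."""
    dens = hist.density()
    model = pdf(hist.centers)
    err = hist.density_errors()
    chi2 = float(np.sum(((dens - model) / err) ** 2))
    occupied = int(np.count_nonzero(hist.counts))
    dof = occupied - n_params
    red = chi2 / dof if dof > 0 else np.inf
    ss_res = float(np.sum((dens - model) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return chi2, red, r2


def fit_single_gamma(
    hist: DiffusionHistogram,
    n_free: bool = True,
    n_fixed: float = 2.0,
    estimates: np.ndarray | None = None,
) -> GammaMixtureFit:
    """One-component gamma fit.

    When raw per-track estimates are supplied, the mean of the fitted gamma
    is anchored at the sample mean — for the gamma family the maximum-
    likelihood estimate of the mean, and unbiased whatever the true shape —
    and only the shape parameter is found by weighted least squares against
    the reflected KDE, with the candidate density convolved with the KDE's
    own kernel so the data-side smoothing does not bias the shape.  Without
    raw estimates both parameters are fitted to the histogram densities
    weighted by Poisson counting error (empty bins weighted as one count).
    χ²/R² always refer to the histogram.  n_free releases the shape
    parameter; otherwise it is fixed at n_fixed.
    """
    if estimates is not None:
        vals = np.asarray(estimates, dtype=float)
        target = _KdeFitTarget(vals)
        d = float(vals.mean())
        if d <= 0:
            raise ValueError("mean diffusion estimate must be positive")
        if n_free:
            def model(xx, n):
                return target.model(gamma_pdf(target.support, d, n))

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, target.grid, target.density, p0=[2.0],
                    sigma=target.sigma, absolute_sigma=True,
                    bounds=([1e-2], [50.0]), maxfev=20000,
                )
            n = float(popt[0])
        else:
            n = float(n_fixed)
        comp = GammaComponent(d, n, 1.0)
        fit = GammaMixtureFit([comp])
        fit.chi2, fit.reduced_chi2, fit.r2 = _hist_gof(
            hist, fit.pdf, 2 if n_free else 1
        )
        return fit

    if np.count_nonzero(hist.counts) < 5:
        raise ValueError("histogram must have at least 5 occupied bins")
    x, y = hist.centers, hist.density()
    sigma = hist.density_errors()
    d0 = max(float(np.sum(x * y) / max(np.sum(y), 1e-12)), hist.bin_width * 0.1)

    best = None
    for d_start in (d0, 2.0 * d0, 0.5 * d0):
        try:
            if n_free:
                def model(xx, d, n):
                    return gamma_pdf(xx, d, n)
                p0 = [d_start, 2.0]
                bounds = ([1e-6, 1e-2], [np.inf, 50.0])
            else:
                def model(xx, d):
                    return gamma_pdf(xx, d, n_fixed)
                p0 = [d_start]
                bounds = ([1e-6], [np.inf])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, x, y, p0=p0, sigma=sigma, absolute_sigma=True,
                    bounds=bounds, maxfev=20000,
                )
            ssr = float(np.sum(((model(x, *popt) - y) / sigma) ** 2))
        except RuntimeError:
            continue
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise RuntimeError("single-gamma fit failed to converge")
    popt = best[0]
    d = float(popt[0])
    n = float(popt[1]) if n_free else float(n_fixed)
    comp = GammaComponent(d, n, 1.0)
    fit = GammaMixtureFit([comp])
    n_params = 2 if n_free else 1
    fit.chi2, fit.reduced_chi2, fit.r2 = _hist_gof(hist, fit.pdf, n_params)
    return fit


@dataclass
class MixtureConstraints:
    """Constraint scheme for the two-component immobile+mobile fit.

    The refined scheme confines the immobile component's D to the first
    histogram bin with a free shape below 1 (steps of an immobile emitter are
    dominated by localization error, hence strongly dependent), and fixes the
    mobile shape at 2 (two non-overlapping steps among the first four).
    """

    immobile_d_max: float | None = None  # default: first bin width
    immobile_n_max: float = 1.0
    mobile_n_fixed: float | None = 2.0
    n_max: float = 4.0  # cap for free shapes in the unconstrained scheme


def fit_mixture(
    hist: DiffusionHistogram,
    n_components: int = 2,
    constraints: MixtureConstraints | None = None,
    estimates: np.ndarray | None = None,
) -> GammaMixtureFit:
    """Gamma-mixture fit with 1-3 components.

    Component weights are fractional prefactors constrained to the unit
    simplex so the fitted density keeps unit area.  With ``constraints`` and
    n_components=2 the refined immobile+mobile scheme is applied (see
    MixtureConstraints); otherwise all D and shape parameters are free and
    positive with shapes capped at constraints.n_max.  Fitting target follows
    fit_single_gamma (reflected KDE when raw estimates are given).
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    cons = constraints or MixtureConstraints()
    if n_components == 1:
        return fit_single_gamma(hist, n_free=True, estimates=estimates)

    if estimates is not None:
        target = _KdeFitTarget(np.asarray(estimates, dtype=float))
        x, y, sigma = target.grid, target.density, target.sigma
    else:
        target = None
        x, y = hist.centers, hist.density()
        sigma = hist.density_errors()

    mean_d = max(float(np.sum(x * y) / max(np.sum(y), 1e-12)), hist.bin_width * 0.1)
    first_bin = cons.immobile_d_max if cons.immobile_d_max is not None else hist.bin_width

    def _wrap(pdf_of_x):
        if target is None:
            return pdf_of_x
        def wrapped(xx, *p):
            return target.model(pdf_of_x(target.support, *p))
        return wrapped

    if n_components == 2 and cons.mobile_n_fixed is not None:
        n_mob = float(cons.mobile_n_fixed)

        def _pdf2(xx, w, d_imm, n_imm, d_mob):
            return w * gamma_pdf(xx, d_imm, n_imm) + (1 - w) * gamma_pdf(xx, d_mob, n_mob)

        model = _wrap(_pdf2)

        lo = [0.0, 1e-6, 1e-2, first_bin]
        hi = [1.0, first_bin, cons.immobile_n_max, np.inf]
        starts = [
            [0.5, 0.5 * first_bin, 0.5, max(mean_d, 1.5 * first_bin)],
            [0.3, 0.5 * first_bin, 0.5, max(2 * mean_d, 2 * first_bin)],
            [0.7, 0.25 * first_bin, 0.3, max(mean_d, 1.5 * first_bin)],
        ]
        n_params = 4

        def unpack(p):
            w, d_imm, n_imm, d_mob = p
            return [
                GammaComponent(float(d_imm), float(n_imm), float(w)),
                GammaComponent(float(d_mob), n_mob, float(1 - w)),
            ]
    else:
        k = n_components
        # free scheme: k densities, k-1 free weights on the simplex
        quantile_d = np.linspace(0.5, 1.5, k) * mean_d

        def _pdfk(xx, *p):
            ws = list(p[: k - 1]) + [1.0 - sum(p[: k - 1])]
            out = np.zeros_like(np.asarray(xx, dtype=float))
            for i in range(k):
                d, n = p[k - 1 + 2 * i], p[k + 2 * i]
                out += ws[i] * gamma_pdf(xx, d, n)
            return out

        model = _pdfk if target is None else _wrap(_pdfk)

        lo = [0.0] * (k - 1) + [1e-6, 1e-2] * k
        hi = [1.0] * (k - 1) + [np.inf, cons.n_max] * k
        starts = [
            [1.0 / k] * (k - 1)
            + [v for d in quantile_d for v in (max(d, 1e-3), 2.0)]
        ]
        n_params = 3 * k - 1

        def unpack(p):
            ws = list(p[: k - 1]) + [1.0 - sum(p[: k - 1])]
            return [
                GammaComponent(float(p[k - 1 + 2 * i]), float(p[k + 2 * i]), float(ws[i]))
                for i in range(k)
            ]

    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, x, y, p0=p0, sigma=sigma, absolute_sigma=True,
                    bounds=(lo, hi), maxfev=40000,
                )
            ssr = float(np.sum(((model(x, *popt) - y) / sigma) ** 2))
        except RuntimeError:
            continue
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise RuntimeError("mixture fit failed to converge")
    fit = GammaMixtureFit(unpack(best[0]))
    fit.chi2, fit.reduced_chi2, fit.r2 = _hist_gof(hist, fit.pdf, n_params)
    return fit


def select_model(fits: dict[int, GammaMixtureFit]) -> int:
    """Component count minimizing reduced χ² (ties to the simpler model)."""
    if not fits:
        raise ValueError("no candidate fits")
    return min(sorted(fits), key=lambda k: (fits[k].reduced_chi2, k))


def iterative_refine(
    estimates: np.ndarray,
    hist: DiffusionHistogram,
    simulator_hook,
    initial_fit: GammaMixtureFit | None = None,
    max_iter: int = 5,
    tol: float = 0.05,
    constraints: MixtureConstraints | None = None,
) -> GammaMixtureFit:
    """Simulation-in-the-loop refinement of the constrained mixture fit.

    Each cycle fits the data, hands the fitted components to simulator_hook —
    which must run the full simulate→track→estimate pipeline and return
    (estimates, histogram) — refits the simulation output under the same
    constraints, and stops once every simulated-fit D matches the simulated
    input D within relative tol.  Non-convergence is flagged on the returned
    (last) fit rather than raised.
    """
    cons = constraints or MixtureConstraints()
    fit = initial_fit or fit_mixture(hist, 2, cons, estimates=estimates)
    converged = False
    for _ in range(max_iter):
        sim_est, sim_hist = simulator_hook(fit.components)
        sim_fit = fit_mixture(sim_hist, 2, cons)
        ok = True
        for c_in, c_out in zip(fit.components, sim_fit.components):
            if abs(c_in.d) <= sim_hist.bin_width:
                # sub-bin (immobile) components are only resolved to within
                # one histogram bin, the scheme's stated constraint
                if c_out.d > sim_hist.bin_width:
                    ok = False
            elif abs(c_out.d - c_in.d) / abs(c_in.d) > tol:
                ok = False
        fit = fit_mixture(hist, 2, cons, estimates=estimates)
        if ok:
            converged = True
            break
    fit.converged = converged
    return fit


def bootstrap_errors(
    estimates: np.ndarray,
    fit_procedure,
    fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """SD of fitted parameters over repeated 80% subsamples (no replacement).

    fit_procedure maps an estimate array to a GammaMixtureFit; returns SDs
    keyed d1, n1, w1, d2, ... in ascending-D component order.
    """
    vals = np.asarray(estimates, dtype=float)
    if vals.size < 10:
        raise ValueError("need at least 10 estimates to bootstrap")
    rng = np.random.default_rng(seed)
    m = max(int(round(fraction * vals.size)), 5)
    samples: dict[str, list[float]] = {}
    for _ in range(repeats):
        sub = rng.choice(vals, size=m, replace=False)
        fit = fit_procedure(sub)
        for i, c in enumerate(fit.components, start=1):
            samples.setdefault(f"d{i}", []).append(c.d)
            samples.setdefault(f"n{i}", []).append(c.n)
            samples.setdefault(f"w{i}", []).append(c.weight)
    return {k: float(np.std(v)) for k, v in samples.items()}
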