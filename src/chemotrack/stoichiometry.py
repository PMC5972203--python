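"""Foci stoichiometry from initial intensity and stepwise photobleaching.

How many dye molecules does a tracked focus carry?  The initial intensity of
a track (back-extrapolated before photobleaching sets in) divided by the
characteristic single-dye intensity gives an apparent stoichiometry; counting
discrete photobleaching steps in the intensity trace gives an independent
integer estimate.  Apparent stoichiometries above one may be genuine
multimers or chance overlaps of two point-spread functions in projection, so
the observed distribution is tested against a spatial-Poisson random-overlap
null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import gaussian_kde

from .tracking import Track

__all__ = [
    "StoichiometryResult",
    "OverlapNull",
    "initial_intensity",
    "single_dye_intensity",
    "apparent_stoichiometries",
    "detect_bleach_steps",
    "chung_kennedy_filter",
    "overlap_null",
    "predicted_intensity_distribution",
    "pearson_chi2",
]


@dataclass
class StoichiometryResult:
    initial_intensities: np.ndarray
    single_dye: float
    stoichiometries: np.ndarray
    bleach_steps: np.ndarray | None = None


@dataclass
class OverlapNull:
    """Random-overlap null: spatial-Poisson nearest-neighbour coincidences.

    p_overlap is the probability that a focus has at least one neighbour
    within the coincidence radius; stoich_pmf[s] (s >= 1) is the predicted
    apparent-stoichiometry probability, Poisson in the number of coincident
    extra emitters.
    """

    p_overlap: float
    lam: float
    stoich_pmf: np.ndarray  # index 0 -> stoichiometry 1

    def pmf_dict(self) -> dict[int, float]:
        return {s + 1: float(p) for s, p in enumerate(self.stoich_pmf)}


def initial_intensity(track: Track) -> float:
    """Initial focus intensity: line through the first three intensity values
    extrapolated to the frame preceding the first observation."""
    if len(track) < 3:
        raise ValueError("track must have at least 3 localizations")
    frames = track.frames[:3].astype(float)
    inten = track.intensities[:3]
    slope, icept = np.polyfit(frames, inten, 1)
    return float(slope * (frames[0] - 1.0) + icept)


def single_dye_intensity(initial_intensities: np.ndarray) -> float:
    """Mode of the kernel density of initial intensities (Silverman rule)."""
    vals = np.asarray(initial_intensities, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 intensities")
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def apparent_stoichiometries(
    tracks: list[Track], single_dye: float | None = None
) -> StoichiometryResult:
    """Per-track apparent stoichiometry = initial intensity / single-dye mode."""
    ii = np.array([initial_intensity(t) for t in tracks if len(t) >= 3])
    if ii.size == 0:
        raise ValueError("no track long enough for an initial intensity")
    mu = single_dye if single_dye is not None else single_dye_intensity(ii)
    if mu <= 0:
        raise ValueError("single-dye intensity must be positive")
    return StoichiometryResult(ii, mu, ii / mu)


def chung_kennedy_filter(trace: np.ndarray, window: int = 5) -> np.ndarray:
    """Edge-preserving filter: at each point take the forward- or
    backward-window mean with the smaller variance, so plateau averaging
    never straddles a step."""
    y = np.asarray(trace, dtype=float)
    n = y.size
    out = np.empty(n)
    for i in range(n):
        back = y[max(i - window, 0): i + 1]
        fwd = y[i: i + window + 1]
        vb = back.var() if back.size > 1 else np.inf
        vf = fwd.var() if fwd.size > 1 else np.inf
        if vb is np.inf and vf is np.inf:
            out[i] = y[i]
        else:
            out[i] = back.mean() if vb <= vf else fwd.mean()
    return out


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return 0.0
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = math.sqrt(va / na + vb / nb)
    if denom == 0:
        return math.inf if a.mean() != b.mean() else 0.0
    return abs(a.mean() - b.mean()) / denom


def _split_points(
    y_filt: np.ndarray, y_raw: np.ndarray, start: int, alpha: float, out: list[int]
) -> None:
    """Recursive change-point search.

    The candidate position comes from the edge-preserving filtered trace
    (sharpest contrast), but significance is judged on the raw trace — the
    filter's running means carry correlated noise that would wildly inflate
    a t statistic computed on it.
    """
    n = y_filt.size
    if n < 4:
        return
    best_t, best_i = 0.0, -1
    for i in range(2, n - 1):
        t = _t_stat(y_filt[:i], y_filt[i:])
        if t > best_t:
            best_t, best_i = t, i
    if best_i < 0:
        return
    t_raw = _t_stat(y_raw[:best_i], y_raw[best_i:])
    dof = max(n - 2, 1)
    # Bonferroni over the candidate split positions within this segment
    p = 2.0 * stats.t.sf(t_raw, dof) * max(n - 3, 1)
    if p >= alpha:
        return
    _split_points(y_filt[:best_i], y_raw[:best_i], start, alpha, out)
    out.append(start + best_i)
    _split_points(y_filt[best_i:], y_raw[best_i:], start + best_i, alpha, out)


def detect_bleach_steps(
    intensity_trace: np.ndarray,
    alpha: float = 1e-4,
    window: int = 5,
    min_plateau: int = 2,
) -> int:
    """Count significant downward intensity steps in a photobleaching trace.

    The trace is Chung-Kennedy filtered, candidate change points are found by
    recursive two-sample t-test segmentation (Bonferroni-corrected within
    segments at level alpha), adjacent plateaus whose means do not differ
    significantly are merged, and the returned count is the number of
    downward transitions between the surviving plateaus.  A flat trace gives
    zero.
    """
    y = np.asarray(intensity_trace, dtype=float)
    if y.size < 5:
        raise ValueError("trace must have at least 5 samples")
    f = chung_kennedy_filter(y, window=window)
    cps: list[int] = []
    _split_points(f, y, 0, alpha, cps)
    edges = [0] + sorted(cps) + [y.size]
    # merge plateaus not significantly different on the raw trace
    plateaus = [y[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a >= min_plateau]
    if len(plateaus) <= 1:
        return 0
    merged = [plateaus[0]]
    for seg in plateaus[1:]:
        t = _t_stat(merged[-1], seg)
        dof = max(merged[-1].size + seg.size - 2, 1)
        if 2.0 * stats.t.sf(t, dof) < 0.01:
            merged.append(seg)
        else:
            merged[-1] = np.concatenate([merged[-1], seg])
    steps = 0
    for a, b in zip(merged[:-1], merged[1:]):
        if b.mean() < a.mean():
            steps += 1
    return steps


def overlap_null(
    max_foci_per_frame: int,
    frame_area_um2: float,
    coincidence_radius_um: float = 0.3,
    max_stoichiometry: int = 12,
) -> OverlapNull:
    """Spatial-Poisson random-overlap null model.

    With emitter density rho = max_foci_per_frame / frame_area, the chance
    that a focus has >= 1 neighbour within the coincidence radius is
    1 - exp(-rho * pi * r²); the apparent stoichiometry 1 + k with k the
    Poisson(rho*pi*r²) number of coincident neighbours, truncated at
    max_stoichiometry and renormalized.
    """
    if max_foci_per_frame <= 0 or frame_area_um2 <= 0 or coincidence_radius_um <= 0:
        raise ValueError("inputs must be positive")
    rho = max_foci_per_frame / frame_area_um2
    lam = rho * math.pi * coincidence_radius_um**2
    p_overlap = 1.0 - math.exp(-lam)
    ks = np.arange(max_stoichiometry)
    pmf = stats.poisson.pmf(ks, lam)
    pmf = pmf / pmf.sum()
    return OverlapNull(p_overlap=p_overlap, lam=lam, stoich_pmf=pmf)


def predicted_intensity_distribution(
    grid: np.ndarray,
    single_dye_density: np.ndarray,
    null: OverlapNull,
    single_dye_mean: float | None = None,
):
    """Predicted focus-intensity density under the random-overlap null.

    Mixture over apparent stoichiometry s of the single-dye density moved to
    mean s*mu and widened by sqrt(s), weighted by the null's stoichiometry
    probabilities.  grid/single_dye_density give the single-dye density
    sampled on a uniform grid (unit area).
    """
    x = np.asarray(grid, dtype=float)
    f1 = np.asarray(single_dye_density, dtype=float)
    dx = x[1] - x[0]
    area = float(f1.sum() * dx)
    if not math.isclose(area, 1.0, rel_tol=5e-2):
        raise ValueError("single_dye_density must integrate to ~1 on grid")
    f1 = f1 / area
    mu = single_dye_mean if single_dye_mean is not None else float((x * f1).sum() * dx)
    out = np.zeros_like(x)
    for s_idx, w in enumerate(null.stoich_pmf):
        s = s_idx + 1
        rs = math.sqrt(s)
        # X_s = mu*s + sqrt(s)*(X1 - mu): density f1((x - s*mu)/rs + mu)/rs
        xi = (x - s * mu) / rs + mu
        fs = np.interp(xi, x, f1, left=0.0, right=0.0) / rs
        out += w * fs
    return out


def pearson_chi2(
    observed_counts: np.ndarray, expected_pmf: np.ndarray
) -> tuple[float, float]:
    """Pearson χ² of observed bin counts against an expected distribution.

    expected_pmf is normalized to the observed total; dof = bins - 1.  Every
    compared bin needs positive expected probability.
    """
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_pmf, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have matching bins")
    if np.any(exp <= 0):
        raise ValueError("expected probabilities must be positive per bin")
    exp_counts = exp / exp.sum() * obs.sum()
    stat = float(np.sum((obs - exp_counts) ** 2 / exp_counts))
    dof = obs.size - 1
    return stat, float(stats.chi2.sf(stat, dof))
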