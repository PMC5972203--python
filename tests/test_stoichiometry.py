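import numpy as np
import pytest

from chemotrack.stoichiometry import (
    apparent_stoichiometries,
    chung_kennedy_filter,
    detect_bleach_steps,
    initial_intensity,
    overlap_null,
    pearson_chi2,
    predicted_intensity_distribution,
    single_dye_intensity,
)
from chemotrack.tracking import Localization, Track


def _track(intensities, start_frame=1):
    locs = [
        Localization(start_frame + i, 0.0, 0.0, float(v), 1.5, 10.0)
        for i, v in enumerate(intensities)
    ]
    return Track(0, locs)


def test_initial_intensity_linear_extrapolation():
    """Line through (1,3000),(2,2800),(3,2600) hits 3200 at frame 0."""
    assert initial_intensity(_track([3000, 2800, 2600])) == pytest.approx(3200.0)


def test_initial_intensity_constant_trace():
    assert initial_intensity(_track([2500, 2500, 2500])) == pytest.approx(2500.0)


def test_initial_intensity_needs_three_points():
    with pytest.raises(ValueError):
        initial_intensity(_track([2500, 2400]))


def test_apparent_stoichiometry_of_multimer():
    """Tracks at s-fold single-dye intensity read out stoichiometry ~s."""
    rng = np.random.default_rng(0)
    mu = 2500.0
    tracks = [_track(mu + rng.normal(0, 50, 4)) for _ in range(300)]
    tracks += [_track(3 * mu + rng.normal(0, 50, 4)) for _ in range(30)]
    res = apparent_stoichiometries(tracks)
    assert res.single_dye == pytest.approx(mu, rel=0.05)
    frac_trimer = np.mean(np.abs(res.stoichiometries - 3.0) < 0.3)
    assert frac_trimer == pytest.approx(30 / 330, abs=0.03)


def test_chung_kennedy_preserves_step_edges():
    trace = np.concatenate([np.full(20, 1000.0), np.zeros(20)])
    filtered = chung_kennedy_filter(trace, window=5)
    # the edge-preserving filter must not smear the transition
    assert filtered[19] == pytest.approx(1000.0)
    assert filtered[20] == pytest.approx(0.0)


def test_bleach_steps_noiseless_two_level():
    trace = np.concatenate([np.full(30, 3000.0), np.zeros(30)])
    assert detect_bleach_steps(trace) == 1


def test_bleach_steps_three_step_staircase():
    """3-step staircase at 10% noise found in >=90% of 100 seeded repeats."""
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(100):
        trace = np.concatenate([
            np.full(30, 3000.0), np.full(30, 2000.0),
            np.full(30, 1000.0), np.full(30, 0.0),
        ]) + rng.normal(0, 100.0, 120)
        if detect_bleach_steps(trace) == 3:
            hits += 1
    assert hits >= 90


def test_bleach_steps_flat_false_positive_rate():
    """Flat traces at SNR >= 5 trigger steps in <5% of repeats."""
    rng = np.random.default_rng(1)
    fp = sum(
        detect_bleach_steps(1000.0 + rng.normal(0, 100.0, 80)) > 0
        for _ in range(200)
    )
    assert fp / 200 < 0.05


def test_bleach_steps_rejects_short_traces():
    with pytest.raises(ValueError):
        detect_bleach_steps(np.ones(4))


def test_overlap_probability_vanishes_at_low_density():
    null = overlap_null(1, 1e6, 0.3)
    assert null.p_overlap == pytest.approx(0.0, abs=1e-6)
    assert null.stoich_pmf[0] == pytest.approx(1.0, abs=1e-6)


def test_overlap_pmf_normalized():
    null = overlap_null(15, 53.4, 0.47)
    assert null.stoich_pmf.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("rho", [0.05, 0.3, 1.0])
def test_overlap_closed_form_matches_point_process(rho):
    """Fraction of foci with a neighbour within r in a uniform scatter
    matches 1 - exp(-rho pi r²) (Monte-Carlo oracle)."""
    rng = np.random.default_rng(int(rho * 100))
    side = 30.0
    r = 0.3
    n = int(round(rho * side * side))
    hits = trials = 0
    for _ in range(300):
        pts = rng.uniform(0, side, size=(n, 2))
        # interior reference points only, to avoid edge bias
        interior = (pts[:, 0] > r) & (pts[:, 0] < side - r) & \
                   (pts[:, 1] > r) & (pts[:, 1] < side - r)
        for i in np.nonzero(interior)[0]:
            d2 = np.sum((pts - pts[i]) ** 2, axis=1)
            d2[i] = np.inf
            trials += 1
            hits += bool((d2 < r * r).any())
    expected = overlap_null(n, side * side, r).p_overlap
    assert trials > 1e4
    se = np.sqrt(expected * (1 - expected) / trials)
    assert abs(hits / trials - expected) < max(3 * se, 0.02 * expected + 1e-4)


def test_predicted_intensity_identity_without_overlap():
    grid = np.linspace(0, 10000, 800)
    mu, sd = 2500.0, 300.0
    f1 = np.exp(-((grid - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))
    null = overlap_null(1, 1e9, 0.3)  # p_overlap ~ 0
    pred = predicted_intensity_distribution(grid, f1, null, single_dye_mean=mu)
    assert np.allclose(pred, f1, atol=1e-6)


def test_predicted_intensity_moment_identity():
    """Mean of the predicted density equals sum_s pmf(s) * s * mu."""
    grid = np.linspace(0, 30000, 3000)
    mu, sd = 2500.0, 250.0
    f1 = np.exp(-((grid - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))
    null = overlap_null(15, 53.4, 0.47)
    pred = predicted_intensity_distribution(grid, f1, null, single_dye_mean=mu)
    dx = grid[1] - grid[0]
    mean_pred = float((grid * pred).sum() * dx)
    expected = mu * sum((s + 1) * p for s, p in enumerate(null.stoich_pmf))
    assert mean_pred == pytest.approx(expected, rel=0.01)


def test_pearson_chi2_hand_example():
    """Observed (10,20,30) vs flat expectation: χ² = 5 + 0 + 5 = 10."""
    stat, p = pearson_chi2(np.array([10.0, 20.0, 30.0]), np.array([1, 1, 1]) / 3)
    assert stat == pytest.approx(10.0)
    assert 0.0 < p < 0.05


def test_pearson_chi2_identical_distributions():
    stat, p = pearson_chi2(np.array([20.0, 20.0, 20.0]), np.array([1, 1, 1]) / 3)
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_pearson_chi2_rejects_mismatched_bins():
    with pytest.raises(ValueError):
        pearson_chi2(np.ones(3), np.ones(4) / 4)
    with pytest.raises(ValueError):
        pearson_chi2(np.ones(3), np.array([0.5, 0.5, 0.0]))


def test_single_dye_mode_from_simulated_brightness():
    """Initial intensities of simulated paper-like tracks peak at 2,000-3,000
    counts."""
    from chemotrack.pipeline import track_stack
    from chemotrack.simulate import SimulationConfig, simulate_stack

    config = SimulationConfig(
        frame_count=150, components=[(0.0, 1.0)], foci_per_frame=6,
        truncation_prob=0.05, seed=12,
    )
    stack, _ = simulate_stack(config)
    tracks = [t for t in track_stack(stack) if len(t) >= 3]
    res = apparent_stoichiometries(tracks)
    assert 2000.0 <= res.single_dye <= 3000.0
    assert single_dye_intensity(res.initial_intensities) == res.single_dye
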