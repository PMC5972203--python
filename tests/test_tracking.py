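import math

import numpy as np
import pytest

from chemotrack.simulate import SimulationConfig, render_gaussian, simulate_stack
from chemotrack.tracking import (
    Localization,
    Track,
    detect_foci,
    detect_stack,
    link_tracks,
    localization_precision,
)
from chemotrack.pipeline import track_stack


def _spot_image(x, y, amplitude=2500.0, sigma=1.2, shape=(32, 32)):
    img = np.zeros(shape)
    total = amplitude  # summed counts
    render_gaussian(img, x, y, total, sigma)
    return img


def test_empty_and_flat_frames_yield_no_detections():
    assert detect_foci(np.zeros((0, 0))) == []
    assert detect_foci(np.zeros((40, 40))) == []


def test_single_spot_subpixel_accuracy():
    """Noise-free Gaussian spot localized within 0.05 px of its center."""
    img = _spot_image(14.30, 7.70, sigma=1.2)
    locs = detect_foci(img, psf_sigma=1.2)
    assert len(locs) == 1
    assert abs(locs[0].x - 14.30) < 0.05
    assert abs(locs[0].y - 7.70) < 0.05
    assert locs[0].intensity > 0


def test_measured_hwhm_in_psf_range():
    """Rendered spots of sigma ~1.95 px have HWHM 250-300 nm at 120 nm/px."""
    img = _spot_image(15.5, 16.5, sigma=1.95, shape=(40, 40))
    locs = detect_foci(img, psf_sigma=1.95)
    assert len(locs) == 1
    hwhm_nm = locs[0].sigma * math.sqrt(2.0 * math.log(2.0)) * 120.0
    assert 250.0 <= hwhm_nm <= 300.0


def test_translation_equivariance():
    img = np.zeros((48, 48))
    render_gaussian(img, 20.35, 22.60, 2500.0, 1.95)
    shifted = np.roll(np.roll(img, 5, axis=0), -3, axis=1)
    a = detect_foci(img, psf_sigma=1.95)
    b = detect_foci(shifted, psf_sigma=1.95)
    assert len(a) == len(b) == 1
    assert b[0].x == pytest.approx(a[0].x - 3, abs=1e-6)
    assert b[0].y == pytest.approx(a[0].y + 5, abs=1e-6)


def test_close_pair_merges_to_brighter():
    img = np.zeros((40, 40))
    render_gaussian(img, 20.0, 20.0, 3000.0, 1.5)
    render_gaussian(img, 22.0, 20.0, 1500.0, 1.5)  # within 2 sigma: merged
    locs = detect_foci(img, psf_sigma=1.5)
    assert len(locs) == 1


def test_ground_truth_recovery_rate(small_mobile_stack):
    """>=95% of interior ground-truth foci recovered within one PSF sigma."""
    stack, truth = small_mobile_stack
    dets = detect_stack(stack)
    px = 0.12
    found = total = 0
    margin = 2 * 1.95
    by_frame = truth.localizations.groupby("frame")
    for frame, group in by_frame:
        dlist = dets[frame]
        for row in group.itertuples():
            x, y = row.x_um / px, row.y_um / px
            if not (margin <= x <= 127 - margin and margin <= y <= 127 - margin):
                continue
            # skip foci with a close neighbour (merged by design)
            same = group[(np.hypot(group.x_um / px - x, group.y_um / px - y) < 4.0)]
            if len(same) > 1:
                continue
            total += 1
            if any(math.hypot(loc.x - x, loc.y - y) < 1.95 for loc in dlist):
                found += 1
    assert total > 200
    assert found / total >= 0.95


def test_linking_single_and_separated_tracks():
    # one detection per frame -> one track
    frames = [[Localization(t, 10.0 + 0.1 * t, 10.0, 100.0, 1.5, 10.0)]
              for t in range(6)]
    tracks = link_tracks(frames, max_step=5.0)
    assert len(tracks) == 1 and len(tracks[0]) == 6
    # two far-apart stationary foci over 10 frames -> exactly two 10-long tracks
    frames = [
        [Localization(t, 5.0, 5.0, 100.0, 1.5, 10.0),
         Localization(t, 100.0, 100.0, 100.0, 1.5, 10.0)]
        for t in range(10)
    ]
    tracks = link_tracks(frames, max_step=5.0)
    assert sorted(len(t) for t in tracks) == [10, 10]


def test_linking_never_reuses_detections():
    rng = np.random.default_rng(0)
    frames = []
    for t in range(20):
        frames.append([
            Localization(t, float(rng.uniform(0, 50)), float(rng.uniform(0, 50)),
                         100.0, 1.5, 10.0)
            for _ in range(8)
        ])
    tracks = link_tracks(frames, max_step=6.0)
    seen = set()
    for tr in tracks:
        for loc in tr.localizations:
            key = (loc.frame, loc.x, loc.y)
            assert key not in seen
            seen.add(key)
        f = tr.frames
        assert (np.diff(f) == 1).all()


def test_linking_rejects_bad_max_step():
    with pytest.raises(ValueError):
        link_tracks([], max_step=0.0)


def test_linked_track_length_matches_truncation():
    """10% per-frame truncation gives geometric track lifetimes of mean 10;
    linked tracks keep only lengths >= 2, whose conditional mean is
    (10 - p)/(1 - p) = 11.0 frames."""
    p = 0.1
    config = SimulationConfig(
        frame_count=1500, components=[(0.0, 1.0)], foci_per_frame=6,
        truncation_prob=p, seed=8,
    )
    stack, _ = simulate_stack(config)
    tracks = track_stack(stack)
    lengths = np.array([len(t) for t in tracks])
    interior = np.array([
        t.frames[0] > 0 and t.frames[-1] < config.frame_count - 1 for t in tracks
    ])
    expected = (1.0 / p - p) / (1.0 - p)
    mean_len = lengths[interior].mean()
    assert abs(mean_len - expected) / expected < 0.10


def test_noiseless_precision_below_6nm(small_static_stack):
    stack, _ = small_static_stack
    tracks = track_stack(stack)
    prec = localization_precision(tracks, stack.pixel_size_nm)
    assert prec < 6.0


def test_precision_requires_enough_localizations():
    tr = Track(0, [Localization(0, 1.0, 1.0, 10.0, 1.5, 5.0),
                   Localization(1, 1.0, 1.0, 10.0, 1.5, 5.0)])
    with pytest.raises(ValueError):
        localization_precision([tr], 120.0)


def test_precision_intensity_scaling():
    """With purely additive readout noise the centroid error scales as the
    noise-to-signal ratio, so 4x intensity cuts the precision ~4-fold."""
    from chemotrack.simulate import NoiseModel
    from chemotrack.pipeline import immobilized_precision_nm

    noise = NoiseModel(base_sd=16.0, intensity_coefficient=0.0)
    p1 = immobilized_precision_nm(
        noise, frame_count=250, seed=19,
        intensity_sampler=lambda rng: 2500.0,
    )
    p4 = immobilized_precision_nm(
        noise, frame_count=250, seed=19,
        intensity_sampler=lambda rng: 10000.0,
    )
    assert p4 < p1
    assert abs(p4 / p1 - 0.25) < 0.12
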