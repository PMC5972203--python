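"""Synthetic fluorescence image stacks of diffusing and immobile emitters.

The simulator emulates a high-frame-rate EMCCD acquisition of isolated
single-molecule foci: each emitter is rendered as a pixel-integrated 2D
Gaussian PSF at its instantaneous continuous position, positions evolve by
Brownian steps of per-axis variance 2*D*dt, and each focus is destroyed and
re-created at a uniform random position with a fixed per-frame probability to
mimic photobleaching and other track-truncation effects.  Readout noise is
zero-mean Gaussian with a per-pixel SD that grows affinely with the local
noise-free intensity.  Motion blur within a frame is deliberately not
rendered; each focus is drawn at a single instantaneous position per frame.

Conventions: pixel centers sit at integer (row, col) = (y, x) coordinates,
0-based; physical position in µm is pixel coordinate × pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "ImageStack",
    "NoiseModel",
    "BackgroundModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_stack",
    "apply_noise",
    "tissue_background_stats",
    "render_gaussian",
]

#: rendering support half-width, in units of the PSF sigma
RENDER_SUPPORT_SIGMA = 5.0


@dataclass
class ImageStack:
    """Time-ordered stack of 2D count images plus acquisition metadata.

    frames has shape (n_frames, rows, cols); pixel_size_nm is the physical
    pixel pitch and frame_interval_s the camera cycle time between frames.
    """

    frames: np.ndarray
    pixel_size_nm: float = 120.0
    frame_interval_s: float = 6.5e-4

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


@dataclass
class NoiseModel:
    """Affine intensity-dependent Gaussian readout noise.

    Per-pixel noise SD = base_sd + intensity_coefficient * (noise-free local
    intensity).  Noise is zero-mean by construction; with both parameters
    zero the stack passes through untouched.
    """

    base_sd: float = 0.0
    intensity_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.base_sd < 0 or self.intensity_coefficient < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def is_zero(self) -> bool:
        return self.base_sd == 0 and self.intensity_coefficient == 0

    def sd_map(self, noise_free: np.ndarray) -> np.ndarray:
        return self.base_sd + self.intensity_coefficient * noise_free


@dataclass
class BackgroundModel:
    """Flat background level plus optional bright static structures.

    static_regions is a binary map (same shape as a frame) of immobile bright
    structures (e.g. autofluorescent extracellular matrix) rendered at
    region_intensity counts above the mean level in every frame.  sd records
    the noise SD measured from control data; it is reporting metadata and does
    not itself add noise (noise is applied through NoiseModel).
    """

    mean_level: float = 0.0
    sd: float = 0.0
    static_regions: np.ndarray | None = None
    region_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_level < 0:
            raise ValueError("mean_level must be >= 0")

    def render(self, frame_shape: tuple[int, int]) -> np.ndarray:
        img = np.full(frame_shape, float(self.mean_level))
        if self.static_regions is not None:
            reg = np.asarray(self.static_regions)
            if reg.shape != frame_shape:
                raise ValueError("static_regions shape does not match frame shape")
            img += self.region_intensity * (reg > 0)
        return img


def _default_intensity(rng: np.random.Generator) -> float:
    # initial summed spot intensities in the 2,000-3,000 count range
    return float(np.clip(rng.normal(2500.0, 250.0), 1200.0, 4500.0))


def _default_width(rng: np.random.Generator) -> float:
    # PSF sigma in pixels; HWHM = sigma*sqrt(2 ln 2) ~ 250-300 nm at 120 nm/px
    return float(np.clip(rng.normal(1.95, 0.08), 1.6, 2.3))


@dataclass
class SimulationConfig:
    """Full description of one simulated acquisition.

    components is a list of (D in µm²/s, number fraction) pairs; fractions
    must sum to 1.  foci_per_frame is the number of concurrently active foci.
    truncation_prob is the per-frame probability that a focus is destroyed and
    re-created elsewhere as a new ground-truth track.
    """

    frame_count: int = 100
    frame_shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 120.0
    frame_interval_s: float = 6.5e-4
    components: list[tuple[float, float]] = field(default_factory=lambda: [(1.6, 1.0)])
    foci_per_frame: int = 8
    intensity_sampler: object = None
    width_sampler: object = None
    truncation_prob: float = 0.1
    noise: NoiseModel = field(default_factory=NoiseModel)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count <= 0:
            raise ValueError("frame_count must be positive")
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob must lie in [0, 1]")
        fracs = np.array([f for _, f in self.components], dtype=float)
        if np.any(fracs < 0):
            raise ValueError("component fractions must be >= 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1 (tolerance 1e-9)")
        if any(d < 0 for d, _ in self.components):
            raise ValueError("every D must be >= 0")

    def sample_intensity(self, rng: np.random.Generator) -> float:
        if self.intensity_sampler is not None:
            return float(self.intensity_sampler(rng))
        return _default_intensity(rng)

    def sample_width(self, rng: np.random.Generator) -> float:
        if self.width_sampler is not None:
            return float(self.width_sampler(rng))
        return _default_width(rng)


GROUND_TRUTH_COLUMNS = [
    "track_id",
    "frame",
    "x_um",
    "y_um",
    "component_D",
    "intensity",
    "sigma_px",
    "in_bounds",
]


@dataclass
class GroundTruth:
    """True emitter trajectories behind a simulated stack.

    localizations is a tidy table with one row per focus per frame
    (columns as in GROUND_TRUTH_COLUMNS); positions are continuous, in µm.
    """

    localizations: pd.DataFrame
    pixel_size_nm: float
    frame_interval_s: float

    def track_positions(self) -> dict[int, np.ndarray]:
        """Map track_id -> (n, 2) array of (x, y) positions in µm."""
        out: dict[int, np.ndarray] = {}
        for tid, g in self.localizations.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            out[int(tid)] = g[["x_um", "y_um"]].to_numpy()
        return out

    def track_lengths(self) -> np.ndarray:
        return self.localizations.groupby("track_id").size().to_numpy()


def render_gaussian(
    img: np.ndarray, x: float, y: float, intensity: float, sigma: float
) -> None:
    """Add a pixel-integrated symmetric 2D Gaussian to img in place.

    x is the column coordinate, y the row coordinate (pixels).  The profile is
    integrated analytically over each pixel (erf form) so the total added
    counts equal `intensity` whenever the support lies inside the frame;
    support is truncated at RENDER_SUPPORT_SIGMA sigma, which discards a
    fraction < 6e-7 of the flux.
    """
    rows, cols = img.shape
    half = RENDER_SUPPORT_SIGMA * sigma
    x0 = max(int(math.floor(x - half)), 0)
    x1 = min(int(math.ceil(x + half)), cols - 1)
    y0 = max(int(math.floor(y - half)), 0)
    y1 = min(int(math.ceil(y + half)), rows - 1)
    if x1 < x0 or y1 < y0:
        return
    s = sigma * math.sqrt(2.0)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    img[y0 : y1 + 1, x0 : x1 + 1] += intensity * np.outer(fy, fx)


class _Focus:
    __slots__ = ("track_id", "x", "y", "D", "intensity", "sigma")

    def __init__(self, track_id, x, y, D, intensity, sigma):
        self.track_id = track_id
        self.x = x
        self.y = y
        self.D = D
        self.intensity = intensity
        self.sigma = sigma


def simulate_stack(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate a fluorescence acquisition; returns the stack and ground truth.

    Deterministic for a fixed config.seed.  The returned stack is noise-free
    if config.noise has zero parameters, otherwise intensity-dependent
    Gaussian readout noise is added and pixel values are clipped at zero
    (a detector cannot report negative counts).
    """
    rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows, cols = config.frame_shape
    px_um = config.pixel_size_nm / 1000.0
    dt = config.frame_interval_s
    comp_d = np.array([d for d, _ in config.components])
    comp_f = np.array([f for _, f in config.components])

    def new_focus(tid: int) -> _Focus:
        x = rng.uniform(0, cols - 1)
        y = rng.uniform(0, rows - 1)
        ci = rng.choice(len(comp_d), p=comp_f)
        return _Focus(
            tid, x, y, float(comp_d[ci]), config.sample_intensity(rng),
            config.sample_width(rng),
        )

    next_id = 0
    foci: list[_Focus] = []
    for _ in range(config.foci_per_frame):
        foci.append(new_focus(next_id))
        next_id += 1

    background = config.background.render((rows, cols))
    frames = np.empty((config.frame_count, rows, cols), dtype=float)
    records: list[tuple] = []

    for t in range(config.frame_count):
        if t > 0:
            for i, f in enumerate(foci):
                if rng.uniform() < config.truncation_prob:
                    foci[i] = new_focus(next_id)
                    next_id += 1
                else:
                    step_sd = math.sqrt(2.0 * f.D * dt) / px_um  # pixels
                    f.x += rng.normal(0.0, step_sd) if step_sd > 0 else 0.0
                    f.y += rng.normal(0.0, step_sd) if step_sd > 0 else 0.0
        img = background.copy()
        for f in foci:
            in_bounds = 0.0 <= f.x <= cols - 1 and 0.0 <= f.y <= rows - 1
            render_gaussian(img, f.x, f.y, f.intensity, f.sigma)
            records.append(
                (f.track_id, t, f.x * px_um, f.y * px_um, f.D, f.intensity,
                 f.sigma, in_bounds)
            )
        frames[t] = img

    stack = ImageStack(frames, config.pixel_size_nm, config.frame_interval_s)
    if not config.noise.is_zero:
        stack = apply_noise(stack, config.noise, rng=noise_rng)
    truth = GroundTruth(
        pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS),
        config.pixel_size_nm,
        config.frame_interval_s,
    )
    return stack, truth


def apply_noise(
    stack: ImageStack,
    noise: NoiseModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Add zero-mean Gaussian readout noise with intensity-dependent SD.

    The per-pixel SD follows noise.sd_map of the noise-free input; negative
    results are clipped to zero.  With a zero NoiseModel the input frames are
    returned unchanged.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise ValueError("stack must be finite-valued")
    if noise.is_zero:
        return ImageStack(frames.copy(), stack.pixel_size_nm, stack.frame_interval_s)
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = noise.sd_map(frames)
    noisy = frames + rng.normal(0.0, 1.0, size=frames.shape) * sd
    np.clip(noisy, 0.0, None, out=noisy)
    return ImageStack(noisy, stack.pixel_size_nm, stack.frame_interval_s)


def tissue_background_stats(
    control_stack: ImageStack, mask: np.ndarray | None = None
) -> BackgroundModel:
    """Mean background level and noise SD from control data, outside the mask.

    mask marks bright static structures (autofluorescent matrix) to exclude;
    statistics are pooled over all frames of the remaining pixels.
    """
    frames = np.asarray(control_stack.frames, dtype=float)
    if mask is None:
        sel = frames.reshape(frames.shape[0], -1)
    else:
        mask = np.asarray(mask) > 0
        if mask.shape != frames.shape[1:]:
            raise ValueError("mask shape must match frame shape")
        keep = ~mask
        if not keep.any():
            raise ValueError("mask excludes every pixel")
        sel = frames[:, keep]
    return BackgroundModel(mean_level=float(sel.mean()), sd=float(sel.std()))
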