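"""Segmentation of bright static (autofluorescent matrix) regions.

Tissue acquisitions contain autofluorescent extracellular-matrix structures
that are bright in every frame.  The temporal intensity average is white
top-hat filtered (disk structuring element, radius 4 px) to flatten diffuse
background, thresholded with Otsu's method, and small holes are filled with a
radius-2 disk.  Tracks are then classified as matrix-bound or interstitial by
majority vote of their localizations against the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion, white_tophat

from .simulate import ImageStack
from .tracking import Track

__all__ = [
    "SegmentationMask",
    "segment_ecm",
    "classify_tracks",
    "mobility_shift_check",
    "fill_small_holes",
]


@dataclass
class SegmentationMask:
    mask: np.ndarray  # bool, frame-shaped
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0

    @property
    def shape(self):
        return self.mask.shape


def fill_small_holes(mask: np.ndarray, radius: int = 2, mode: str = "erode_dilate_inverted") -> np.ndarray:
    """Fill small holes in a binary mask with a disk of the given radius.

    ``erode_dilate_inverted`` applies erosion-then-dilation to the hole
    (background) topology, which on the foreground is a binary closing;
    ``closing`` applies dilation-then-erosion to the foreground directly.
    Both fill holes narrower than ~2*radius; the switch exists because
    erosion-first on the foreground itself (an opening) cannot fill holes.
    """
    se = disk(radius)
    if mode == "erode_dilate_inverted":
        inv = ~mask
        inv = dilation(erosion(inv, se), se) > 0
        return ~inv
    if mode == "closing":
        return erosion(dilation(mask, se), se) > 0
    raise ValueError(f"unknown mode {mode!r}")


def segment_ecm(
    stack: ImageStack,
    tophat_radius: int = 4,
    hole_radius: int = 2,
    hole_mode: str = "erode_dilate_inverted",
) -> SegmentationMask:
    """Segment bright static structures from a stack's temporal average.

    Pipeline: temporal mean → white top-hat (disk of tophat_radius) → Otsu
    threshold → small-hole filling (disk of hole_radius).  Note the top-hat
    passes only structures narrower than roughly twice its radius; broad
    plateaus are treated as background.  A constant image has no Otsu
    threshold and yields an empty mask with a warning.
    """
    frames = np.asarray(stack.frames, dtype=float)
    avg = frames.mean(axis=0)
    if np.ptp(avg) == 0:
        warnings.warn("constant average image; returning empty mask")
        return SegmentationMask(np.zeros(avg.shape, dtype=bool),
                                {"tophat_radius": tophat_radius})
    filtered = white_tophat(avg, footprint=disk(tophat_radius))
    if np.ptp(filtered) == 0:
        warnings.warn("top-hat output constant; returning empty mask")
        return SegmentationMask(np.zeros(avg.shape, dtype=bool),
                                {"tophat_radius": tophat_radius})
    thresh = threshold_otsu(filtered)
    binary = filtered > thresh
    binary = fill_small_holes(binary, hole_radius, hole_mode)
    return SegmentationMask(
        binary,
        {"tophat_radius": tophat_radius, "hole_radius": hole_radius,
         "hole_mode": hole_mode, "otsu_threshold": float(thresh)},
    )


def classify_tracks(tracks: list[Track], mask: SegmentationMask) -> list[str]:
    """Label each track "ECM" or "interstitial" by localization majority vote.

    A localization votes for the matrix if its nearest pixel is inside the
    mask; ties go to "ECM" (conservative: ambiguous tracks are excluded from
    the mobile population).
    """
    m = mask.mask
    rows, cols = m.shape
    labels = []
    for tr in tracks:
        votes = 0
        n = len(tr)
        for loc in tr.localizations:
            r = min(max(int(round(loc.y)), 0), rows - 1)
            c = min(max(int(round(loc.x)), 0), cols - 1)
            votes += bool(m[r, c])
        labels.append("ECM" if votes * 2 >= n else "interstitial")
    return labels


def mobility_shift_check(d_sample_a: np.ndarray, d_sample_b: np.ndarray):
    """One-sided rank-sum test that sample B is shifted to higher mobility.

    Returns (direction, p_value) where direction is "higher" when sample B's
    diffusion coefficients are stochastically larger than sample A's.
    Requires at least 5 values per sample.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(d_sample_a, dtype=float)
    b = np.asarray(d_sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values per sample")
    stat, p = mannwhitneyu(b, a, alternative="greater")
    direction = "higher" if np.median(b) >= np.median(a) else "lower"
    return direction, float(p)
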