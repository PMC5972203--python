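"""File formats: multi-page TIFF stacks, track tables, configs, manifests.

Stacks are stored as 16-bit unsigned multi-page TIFFs of raw counts; pixel
size and frame interval are acquisition metadata supplied by the caller (or a
config file), never guessed from TIFF tags.  Track tables are CSV with a
fixed schema; µm columns are derived from pixel columns at write time so the
two can never disagree.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth, ImageStack
from .tracking import Localization, Track

__all__ = [
    "read_stack",
    "write_stack",
    "tracks_to_frame",
    "frame_to_tracks",
    "write_tracks",
    "read_tracks",
    "write_ground_truth",
    "write_manifest",
]

TRACK_COLUMNS = [
    "track_id", "frame", "x_px", "y_px", "x_um", "y_um",
    "intensity", "sigma_px", "snr",
]


def read_stack(
    path, pixel_size_nm: float = 120.0, frame_interval_s: float = 6.5e-4
) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack (frames in page order)."""
    frames = tifffile.imread(str(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("expected a 2D image or a multi-page stack")
    return ImageStack(frames.astype(float), pixel_size_nm, frame_interval_s)


def write_stack(path, stack: ImageStack) -> None:
    """Write frames as 16-bit unsigned counts (clipped and rounded)."""
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def tracks_to_frame(
    tracks: list[Track], pixel_size_nm: float, labels: list[str] | None = None
) -> pd.DataFrame:
    rows = []
    scale = pixel_size_nm / 1000.0
    for i, tr in enumerate(tracks):
        lab = labels[i] if labels is not None else None
        for loc in tr.localizations:
            row = {
                "track_id": tr.id, "frame": loc.frame,
                "x_px": loc.x, "y_px": loc.y,
                "x_um": loc.x * scale, "y_um": loc.y * scale,
                "intensity": loc.intensity, "sigma_px": loc.sigma,
                "snr": loc.snr,
            }
            if lab is not None:
                row["label"] = lab
            rows.append(row)
    cols = TRACK_COLUMNS + (["label"] if labels is not None else [])
    return pd.DataFrame(rows, columns=cols)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        locs = [
            Localization(int(r.frame), float(r.x_px), float(r.y_px),
                         float(r.intensity), float(r.sigma_px), float(r.snr))
            for r in g.itertuples()
        ]
        tracks.append(Track(int(tid), locs))
    return tracks


def write_tracks(
    path, tracks: list[Track], pixel_size_nm: float,
    labels: list[str] | None = None,
) -> None:
    tracks_to_frame(tracks, pixel_size_nm, labels).to_csv(path, index=False)


def read_tracks(path) -> tuple[list[Track], pd.DataFrame]:
    """Read a track CSV; returns (tracks, full table incl. extra columns)."""
    df = pd.read_csv(path)
    return frame_to_tracks(df), df


def write_ground_truth(path, truth: GroundTruth) -> None:
    truth.localizations.to_csv(path, index=False)


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Record the parameters and seed of a run next to its outputs."""
    import chemotrack

    payload = {
        "package": "chemotrack",
        "version": chemotrack.__version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
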