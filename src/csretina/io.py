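"""Reading and writing of movies and trace sets.

Stimulus and imaging movies travel as multi-page TIFF (one page per frame)
with a JSON sidecar (``<name>.json``) holding geometry, masks and condition
annotations; trace sets are stored in HDF5 with a JSON parameter attribute.
An optional loader accepts user-supplied 8-bit grayscale image sequences.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .roi_pipeline import ConditionSegment, ImagingMovie
from .stimuli import StimulusMovie
from .traces import TraceSet

__all__ = [
    "save_stimulus_movie",
    "load_stimulus_movie",
    "save_traces_h5",
    "load_traces_h5",
    "save_imaging_movie",
    "load_imaging_movie",
    "load_image_sequence",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stimulus_movie(movie: StimulusMovie, path: str | Path) -> Path:
    """Write frames as multi-page TIFF (time as pages) plus JSON sidecar."""
    path = Path(path)
    # pages x (y,) x spatial: move time first
    frames = np.moveaxis(movie.frames, -1, 0).astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = {
        "dx": movie.dx,
        "dt": movie.dt,
        "background": movie.background,
        "mask_regions": [list(r) for r in movie.mask_regions],
        "condition_label": movie.condition_label,
        "emergence_site": movie.emergence_site,
        "emergence_time_ms": movie.emergence_time_ms,
        "full_emergence_site": movie.full_emergence_site,
        "is_2d": movie.is_2d,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_stimulus_movie(path: str | Path) -> StimulusMovie:
    path = Path(path)
    frames = np.moveaxis(tifffile.imread(path), 0, -1).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    if not meta.get("is_2d", frames.ndim == 3) and frames.ndim == 3:
        frames = frames[0]
    movie = StimulusMovie(
        frames,
        dx=meta["dx"],
        dt=meta["dt"],
        background=meta.get("background", 0.0),
        mask_regions=[tuple(r) for r in meta.get("mask_regions", [])],
        condition_label=meta.get("condition_label", "motion_full"),
    )
    if meta.get("emergence_site") is not None:
        movie.emergence_site = tuple(meta["emergence_site"])
        movie.emergence_time_ms = meta.get("emergence_time_ms")
    if meta.get("full_emergence_site") is not None:
        movie.full_emergence_site = tuple(meta["full_emergence_site"])
    return movie


def save_traces_h5(
    traces: dict[str, TraceSet] | TraceSet, path: str | Path, params: dict | None = None
) -> Path:
    """Store one or several trace sets as HDF5 datasets (+ JSON params attr)."""
    import h5py

    path = Path(path)
    if isinstance(traces, TraceSet):
        traces = {"traces": traces}
    with h5py.File(path, "w") as f:
        for name, ts in traces.items():
            g = f.create_group(name)
            g.create_dataset("values", data=ts.values)
            if ts.positions is not None:
                g.create_dataset("positions", data=ts.positions)
            g.attrs["dt"] = ts.dt
            g.attrs["condition_label"] = ts.condition_label
        if params:
            f.attrs["params"] = json.dumps(params)
    return path


def load_traces_h5(path: str | Path) -> dict[str, TraceSet]:
    import h5py

    out: dict[str, TraceSet] = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            out[name] = TraceSet(
                g["values"][()],
                dt=float(g.attrs["dt"]),
                positions=g["positions"][()] if "positions" in g else None,
                condition_label=str(g.attrs.get("condition_label", "")),
            )
    return out


def save_imaging_movie(movie: ImagingMovie, path: str | Path) -> Path:
    path = Path(path)
    data = movie.data
    if data.ndim == 3:
        pages = np.moveaxis(data, -1, 0).astype(np.float32)
    else:  # repeats kept as separate series axis
        pages = np.moveaxis(data, -1, 1).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "um_per_px": movie.um_per_px,
        "frame_hz": movie.frame_hz,
        "segments": [asdict(s) for s in movie.segments],
        "baseline": list(movie.baseline) if movie.baseline else None,
        "is_dff": movie.is_dff,
        "has_repeats": data.ndim == 4,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_imaging_movie(path: str | Path) -> ImagingMovie:
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("has_repeats"):
        data = np.moveaxis(pages, 1, -1)
    else:
        data = np.moveaxis(pages, 0, -1)
    return ImagingMovie(
        data,
        um_per_px=meta["um_per_px"],
        frame_hz=meta["frame_hz"],
        segments=[ConditionSegment(**s) for s in meta.get("segments", [])],
        baseline=tuple(meta["baseline"]) if meta.get("baseline") else None,
        is_dff=meta.get("is_dff", False),
    )


def load_image_sequence(
    paths: list[str | Path], dx: float, dt: float, background: float = 128.0
) -> StimulusMovie:
    """Build a stimulus movie from user-supplied 8-bit grayscale images."""
    import imageio.v3 as iio

    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        frames.append(img)
    stack = np.stack(frames, axis=-1)
    return StimulusMovie(
        stack, dx=dx, dt=dt, background=background, condition_label="natural_movie"
    )
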