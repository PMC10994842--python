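"""Readers and writers: ImageJ-style TIFF movies, CSV tables, JSON results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth


def write_movie_tiff(path, movie: np.ndarray, pixel_size_nm: float,
                     frame_interval_s: float) -> None:
    """Write a (T, H, W) uint16 stack with ImageJ-compatible metadata."""
    path = Path(path)
    px_um = pixel_size_nm / 1000.0
    tifffile.imwrite(
        path, movie, imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={"axes": "TYX", "unit": "um",
                  "finterval": frame_interval_s})


def read_movie_tiff(path) -> tuple:
    """Read a movie stack; returns (movie, pixel_size_nm, frame_interval_s).

    Metadata fall back to 65 nm / 1 s when the file carries none.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        movie = tf.asarray()
        px_nm, dt = 65.0, 1.0
        try:
            tags = tf.pages[0].tags
            xr = tags["XResolution"].value
            px_nm = 1000.0 * xr[1] / xr[0]
        except (KeyError, ZeroDivisionError, TypeError):
            pass
        meta = tf.imagej_metadata or {}
        dt = float(meta.get("finterval", dt))
    if movie.ndim == 2:
        movie = movie[None]
    return movie, px_nm, dt


def write_truth_json(path, truth: GroundTruth) -> None:
    Path(path).write_text(truth.to_json())


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten tracks into a tidy table (one row per spot)."""
    rows = []
    for tr in tracks:
        for s in tr.spots:
            rows.append({"track_id": tr.id, "frame": s.frame,
                         "theta_deg": s.theta, "x_px": s.x, "y_px": s.y,
                         "intensity": s.amplitude})
    return pd.DataFrame(rows)


def segments_to_frame(segments) -> pd.DataFrame:
    rows = [{"track_id": s.track_id, "state": s.state, "t0": s.start_time,
             "t1": s.end_time, "speed_nm_s": s.speed,
             "end_cause": s.end_cause, "censored": s.censored}
            for s in segments]
    return pd.DataFrame(rows)


def write_json(path, obj) -> None:
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, default=enc, indent=1))
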