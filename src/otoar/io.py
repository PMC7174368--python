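"""File I/O: PNG frame sequences, truth tables, points files, logs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .synthetic import SyntheticDataset

__all__ = [
    "save_dataset",
    "load_frames",
    "load_points_csv",
    "save_points_csv",
]


def save_dataset(ds: SyntheticDataset, out_dir, max_frames: int | None = None) -> Path:
    """Write a dataset to disk: frames/NNNNN.png, ct_render.png,
    intrinsics.yaml, truth.csv, fiducials files."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    n = len(ds) if max_frames is None else min(len(ds), max_frames)
    for i in range(n):
        iio.imwrite(out / "frames" / f"{i:05d}.png", ds.frame(i))
    iio.imwrite(out / "ct_render.png", ds.ct_render)
    ds.intrinsics.to_file(out / "intrinsics.yaml")
    rows = []
    for gt in ds.truths[:n]:
        row = {
            "frame": gt.frame_index,
            "time_s": gt.time_s,
            "instrument_present": int(gt.instrument_present),
        }
        for r in range(3):
            for c in range(3):
                row[f"H{r}{c}"] = gt.true_plane_homography.matrix[r, c]
        for k, (x, y) in enumerate(gt.fiducial_px):
            row[f"fid{k}_x"], row[f"fid{k}_y"] = x, y
        if gt.instrument_present:
            for lbl in "bcd":
                row[f"{lbl}_x"], row[f"{lbl}_y"] = gt.marker_px[lbl]
            row["tip_X_mm"], row["tip_Y_mm"], row["tip_Z_mm"] = gt.tip_3d_mm
            row["tip_px_x"], row["tip_px_y"] = gt.tip_px
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
    save_points_csv(out / "ct_markers.csv", ds.ct_marker_px)
    save_points_csv(out / "reference_fiducials.csv", ds.reference_fiducials_px)
    with open(out / "scene.json", "w") as fh:
        json.dump({"seed": ds.spec.seed, "px_per_mm": ds.spec.px_per_mm,
                   "fps": ds.spec.fps, "duration_s": ds.spec.duration_s,
                   "n_fiducials": ds.spec.n_fiducials}, fh, indent=2)
    return out


def load_frames(dir_or_file) -> list[np.ndarray]:
    """Read an image-sequence directory (sorted) or a single image."""
    p = Path(dir_or_file)
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() in
                       {".png", ".tif", ".tiff", ".jpg", ".jpeg"})
        if not files:
            raise ConfigError(f"no image files in {p}")
        return [iio.imread(f) for f in files]
    if not p.exists():
        raise ConfigError(f"input not found: {p}")
    return [iio.imread(p)]


def load_points_csv(path) -> np.ndarray:
    """Points file (CSV with x,y columns, optional marker_id) -> (n, 2)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ConfigError(f"points file {path} needs x and y columns")
    if "marker_id" in cols:
        df = df.sort_values(cols["marker_id"])
    return df[[cols["x"], cols["y"]]].to_numpy(dtype=float)


def save_points_csv(path, points: np.ndarray) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pd.DataFrame({"marker_id": np.arange(len(pts)),
                  "x": pts[:, 0], "y": pts[:, 1]}).to_csv(path, index=False)
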