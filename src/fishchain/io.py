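"""File formats: pose/tracklet CSV dialects, frame directories, YAML configs.

The pose CSV has one row per fish per frame with columns
``frame, id, N_x, N_y, G_x, G_y, J1_x..J{n-1}_y, O_x, O_y,
theta_1..theta_n, cover_ratio``; tracklet files reuse it (the id column
is the tracklet id).  Ground-truth files carry at least
``frame, id, nose_x, nose_y``; the occlusion log carries
``start_frame, end_frame, ids`` with ids joined by ``|``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage import io as skio

from .model import FishPose, RectangleSpec
from .relinking import Tracklet

__all__ = [
    "poses_to_frame_table",
    "tracklets_to_table",
    "table_to_tracklets",
    "write_tracklets",
    "read_tracklets",
    "read_frames",
    "write_frames",
    "load_config_file",
    "dump_config_file",
]


def _pose_row(pose: FishPose, ident: int) -> dict:
    row = {
        "frame": pose.frame, "id": ident,
        "N_x": pose.N[0], "N_y": pose.N[1],
        "G_x": pose.G[0], "G_y": pose.G[1],
    }
    for k in range(len(pose.J)):
        row[f"J{k + 1}_x"] = pose.J[k, 0]
        row[f"J{k + 1}_y"] = pose.J[k, 1]
    row["O_x"] = pose.O[0]
    row["O_y"] = pose.O[1]
    for k in range(len(pose.theta)):
        row[f"theta_{k + 1}"] = pose.theta[k]
    row["cover_ratio"] = pose.cover_ratio
    row["coasted"] = int(pose.coasted)
    return row


def _row_pose(row) -> FishPose:
    j_cols = sorted(
        (c for c in row.index if re.fullmatch(r"J\d+_x", c)),
        key=lambda c: int(c[1:-2]),
    )
    J = np.array([[row[c], row[c[:-2] + "_y"]] for c in j_cols])
    th_cols = sorted(
        (c for c in row.index if re.fullmatch(r"theta_\d+", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    return FishPose(
        G=np.array([row["G_x"], row["G_y"]]),
        N=np.array([row["N_x"], row["N_y"]]),
        J=J,
        O=np.array([row["O_x"], row["O_y"]]),
        theta=np.array([row[c] for c in th_cols]),
        cover_ratio=float(row.get("cover_ratio", np.nan)),
        frame=int(row["frame"]),
        coasted=bool(int(row.get("coasted", 0))),
    )


def poses_to_frame_table(poses_by_frame: list[list[FishPose]]) -> pd.DataFrame:
    """Detection output: per-frame pose lists to the pose CSV dialect."""
    rows = []
    for frame_poses in poses_by_frame:
        for i, p in enumerate(frame_poses):
            rows.append(_pose_row(p, i))
    return pd.DataFrame(rows)


def tracklets_to_table(tracklets: list[Tracklet]) -> pd.DataFrame:
    rows = []
    for t in tracklets:
        for p in t.poses:
            rows.append(_pose_row(p, t.id))
    return pd.DataFrame(rows)


def table_to_tracklets(df: pd.DataFrame) -> list[Tracklet]:
    out = []
    for ident, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("frame")
        poses = [_row_pose(r) for _, r in grp.iterrows()]
        out.append(Tracklet(id=int(ident), poses=poses))
    out.sort(key=lambda t: (t.st, t.id))
    return out


def write_tracklets(tracklets: list[Tracklet], path) -> None:
    tracklets_to_table(tracklets).to_csv(path, index=False, float_format="%.4f")


def read_tracklets(path) -> list[Tracklet]:
    return table_to_tracklets(pd.read_csv(path))


_FRAME_EXTS = (".png", ".bmp", ".tif", ".tiff")


def read_frames(directory) -> tuple[np.ndarray, list[str]]:
    """Load a numbered frame directory into a (T, H, W) grayscale stack."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _FRAME_EXTS
    )
    if not files:
        raise FileNotFoundError(f"no frame images in {directory}")
    stack = []
    for p in files:
        img = skio.imread(p)
        if img.ndim == 3:
            img = img.mean(axis=2)
        stack.append(np.asarray(img))
    shapes = {a.shape for a in stack}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched dimensions: {shapes}")
    return np.stack(stack), [p.name for p in files]


def write_frames(frames: np.ndarray, directory, prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(len(str(len(frames) - 1)), 5)
    paths = []
    for t, img in enumerate(frames):
        p = directory / f"{prefix}_{t:0{width}d}.png"
        skio.imsave(p, np.asarray(img, dtype=np.uint8), check_contrast=False)
        paths.append(p)
    return paths


def load_config_file(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_config_file(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
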