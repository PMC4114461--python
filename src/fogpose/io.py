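"""Plain-text I/O: rig calibration files, IMU CSV streams, 16-bit PGM
depth rasters, trajectory and truth tables."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Plane, TrackingFrame, make_tracking_frame

__all__ = [
    "write_rig_calibration",
    "read_rig_calibration",
    "read_imu_csv",
    "write_imu_csv",
    "write_pgm16",
    "read_pgm16",
    "write_template_csv",
    "read_template_csv",
]

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]


def write_rig_calibration(path, plane: Plane, camera_origin, camera_forward, psi_deg):
    """Key-value rig calibration: floor plane, camera pose, psi."""
    lines = [
        "# fogpose rig calibration",
        "plane_normal = " + " ".join(f"{v:.9g}" for v in plane.normal),
        f"plane_offset = {plane.offset:.9g}",
        "camera_origin = " + " ".join(f"{v:.9g}" for v in np.asarray(camera_origin, float)),
        "camera_forward = " + " ".join(f"{v:.9g}" for v in np.asarray(camera_forward, float)),
        f"psi_deg = {float(psi_deg):.9g}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rig_calibration(path) -> TrackingFrame:
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = np.array([float(v) for v in val.split()])
    plane = Plane(normal=values["plane_normal"], offset=float(values["plane_offset"][0]))
    return make_tracking_frame(
        plane,
        values["camera_origin"],
        values["camera_forward"],
        psi_deg=float(values["psi_deg"][0]),
    )


def write_imu_csv(path, df: pd.DataFrame):
    cols = [c for c in IMU_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_imu_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV missing required columns: {missing}")
    return df


def write_template_csv(path, templates, labels):
    """Height-template dataset: 441 pixel columns + the two scalar
    features + the class label."""
    feats = np.array([t.feature_vector() for t in templates])
    cols = (
        [f"p{i:03d}" for i in range(441)]
        + ["norm_constant", "nonzero_count"]
    )
    df = pd.DataFrame(feats, columns=cols)
    df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False)


def read_template_csv(path):
    """Returns ``(features (N, 443), labels (N,))``."""
    df = pd.read_csv(path)
    if "label" not in df.columns or df.shape[1] != 444:
        raise ValueError("template CSV must have 443 feature columns plus a label")
    labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels


def write_pgm16(path, depth_mm: np.ndarray):
    """Binary 16-bit PGM (P5, big-endian), mm depth, 0 = invalid."""
    depth_mm = np.asarray(depth_mm)
    h, w = depth_mm.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n65535\n".encode())
        fh.write(depth_mm.astype(">u2").tobytes())


def read_pgm16(path) -> np.ndarray:
    data = Path(path).read_bytes()
    m = re.match(rb"P5\s+(\d+)\s+(\d+)\s+(\d+)\s", data)
    if not m:
        raise ValueError(f"{path} is not a binary PGM file")
    w, h, maxval = (int(g) for g in m.groups())
    dtype = ">u2" if maxval > 255 else "u1"
    arr = np.frombuffer(data[m.end() :], dtype=dtype, count=w * h)
    return arr.reshape(h, w).astype(np.uint16)
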