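"""Stop-window segmentation and accuracy statistics.

The accuracy protocol extracts a ~1 s window of estimates each time a
participant stands still on a marked reference point, keeps windows whose
per-coordinate standard deviation is below 0.04 (m), and aggregates the
window means against the marker reference values per point and per
participant: average value, mean (signed) error, RMSE and maximum
absolute error. Angular errors use the minimal signed difference and
angular averages use the circular mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import signed_angle_diff, wrap_heading

__all__ = [
    "segment_stops",
    "per_point_stats",
    "per_participant_stats",
    "position_per_point_stats",
    "overall_position_rmse",
    "circular_mean_deg",
    "circular_std_deg",
]

POSITION_STD_MAX = 0.04  # m, the acceptance rule for a stop window
HEADING_STD_MAX = 15.0  # deg, gate for heading windows


def circular_mean_deg(angles) -> float:
    a = np.radians(np.asarray(angles, dtype=float))
    return wrap_heading(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def circular_std_deg(angles) -> float:
    """Angular spread: RMS of signed deviations from the circular mean."""
    angles = np.asarray(angles, dtype=float)
    mu = circular_mean_deg(angles)
    dev = np.array([signed_angle_diff(x, mu) for x in angles])
    return float(np.sqrt(np.mean(dev**2)))


def segment_stops(
    trajectory: pd.DataFrame,
    truth: pd.DataFrame,
    window: float = 1.0,
    pos_std_max: float = POSITION_STD_MAX,
    heading_std_max: float = HEADING_STD_MAX,
    heading_columns=("theta",),
    min_samples: int = 5,
) -> pd.DataFrame:
    """Extract a centered ~1 s window of estimates for every truth stop.

    ``trajectory`` needs columns t, x, y and optionally heading columns
    (deg; NaN = withheld). Windows whose positional std exceeds the
    acceptance rule are flagged rejected (recorded, excluded from stats);
    heading windows are gated separately per heading column.

    Returns one row per (truth stop x quantity-acceptance) with the
    window means and flags.
    """
    if len(trajectory) == 0 or trajectory["t"].max() < truth["t_start"].min():
        import warnings

        warnings.warn("trajectory does not overlap the truth stop intervals")
    rows = []
    t = trajectory["t"].to_numpy()
    for _, stop in truth.iterrows():
        center = 0.5 * (stop["t_start"] + stop["t_end"])
        sel = (t >= center - window / 2) & (t <= center + window / 2)
        sub = trajectory.loc[sel]
        row = {
            k: stop[k]
            for k in ("participant", "condition", "walk", "point_id")
            if k in stop
        }
        row.update(
            ref_x=stop["x"], ref_y=stop["y"], ref_heading=stop.get("heading", np.nan)
        )
        pos = sub[["x", "y"]].dropna()
        if len(pos) >= min_samples:
            sx, sy = pos["x"].std(ddof=0), pos["y"].std(ddof=0)
            row.update(
                est_x=pos["x"].mean(),
                est_y=pos["y"].mean(),
                pos_std=max(sx, sy),
                pos_accepted=bool(sx < pos_std_max and sy < pos_std_max),
            )
        else:
            row.update(est_x=np.nan, est_y=np.nan, pos_std=np.nan, pos_accepted=False)
        for col in heading_columns:
            if col not in sub.columns:
                continue
            h = sub[col].dropna()
            if len(h) >= min_samples:
                mu = circular_mean_deg(h)
                sd = circular_std_deg(h)
                row[f"est_{col}"] = mu
                row[f"{col}_std"] = sd
                row[f"{col}_accepted"] = bool(sd < heading_std_max)
            else:
                row[f"est_{col}"] = np.nan
                row[f"{col}_std"] = np.nan
                row[f"{col}_accepted"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def _error_stats(errors: np.ndarray) -> dict:
    errors = np.asarray(errors, dtype=float)
    return dict(
        n=len(errors),
        mean_error=float(errors.mean()),
        rmse=float(np.sqrt(np.mean(errors**2))),
        max_error=float(np.abs(errors).max()),
    )


def position_per_point_stats(windows: pd.DataFrame) -> pd.DataFrame:
    """Per reference point, per coordinate: reference value, average
    estimate, mean error, RMSE, max |error| over accepted windows."""
    acc = windows[windows["pos_accepted"]]
    rows = []
    for pid, grp in acc.groupby("point_id"):
        for coord in ("x", "y"):
            err = (grp[f"est_{coord}"] - grp[f"ref_{coord}"]).to_numpy()
            rows.append(
                dict(
                    point_id=pid,
                    coordinate=coord,
                    ref_value=grp[f"ref_{coord}"].iloc[0],
                    avg_value=float(grp[f"est_{coord}"].mean()),
                    **_error_stats(err),
                )
            )
    return pd.DataFrame(rows)


def per_point_stats(windows: pd.DataFrame, column: str = "theta") -> pd.DataFrame:
    """Heading statistics aggregated per reference point over
    participants (the per-marker tables)."""
    flag = f"{column}_accepted"
    if flag not in windows.columns:
        return pd.DataFrame()
    acc = windows[windows[flag].fillna(False).astype(bool)]
    rows = []
    for pid, grp in acc.groupby("point_id"):
        est = grp[f"est_{column}"].to_numpy()
        ref = grp["ref_heading"].to_numpy()
        err = np.array([signed_angle_diff(e, r) for e, r in zip(est, ref)])
        rows.append(
            dict(
                point_id=pid,
                ref_angle=ref[0],
                avg_angle=circular_mean_deg(est),
                **_error_stats(err),
            )
        )
    return pd.DataFrame(rows)


def per_participant_stats(windows: pd.DataFrame, column: str = "theta") -> pd.DataFrame:
    """Heading statistics aggregated per participant over that person's
    stop points (the attachment-comparison tables)."""
    flag = f"{column}_accepted"
    if flag not in windows.columns:
        return pd.DataFrame()
    acc = windows[windows[flag].fillna(False).astype(bool)]
    rows = []
    for part, grp in acc.groupby("participant"):
        err = np.array(
            [
                signed_angle_diff(e, r)
                for e, r in zip(grp[f"est_{column}"], grp["ref_heading"])
            ]
        )
        rows.append(dict(participant=part, **_error_stats(err)))
    return pd.DataFrame(rows)


def overall_position_rmse(windows: pd.DataFrame) -> dict:
    """Per-coordinate RMSE over all accepted stop windows; the headline
    accuracy is the larger of the two."""
    acc = windows[windows["pos_accepted"]]
    ex = (acc["est_x"] - acc["ref_x"]).to_numpy()
    ey = (acc["est_y"] - acc["ref_y"]).to_numpy()
    rmse_x = float(np.sqrt(np.mean(ex**2)))
    rmse_y = float(np.sqrt(np.mean(ey**2)))
    return dict(
        rmse_x=rmse_x,
        rmse_y=rmse_y,
        rmse=max(rmse_x, rmse_y),
        n_windows=len(acc),
        n_rejected=int((~windows["pos_accepted"]).sum()),
    )
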