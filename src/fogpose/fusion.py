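"""Person-heading estimation from the worn device.

Two methods are implemented. *Method1* assumes the device is worn in a
known orientation on the left hip: the absolute (MARG) filter gives the
device yaw against magnetic North (alpha), which two rig-calibrated
corrections turn into the person's heading in the camera tracking frame,

    theta = wrap(alpha - psi + 90),

where psi is the angle from magnetic North to the camera's yc-axis (all
angles counterclockwise viewed from above, degrees).

*Method2* makes no mounting assumption. The gravity-relative filter
tracks the projected device y-axis angle theta_i (in an arbitrary yaw
gauge); when the vision classifier's *static heading* agrees with the
track-velocity *dynamic heading* within a bound for several consecutive
frames, the static heading is confirmed as the external reference
theta_s, the correction angle delta_c = theta_i - theta_s is latched, and
from then on theta = wrap(theta_i - delta_c). The correction angle
absorbs the mount offset and the gauge freedom in one constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import signed_angle_diff, wrap_heading

__all__ = [
    "HeadingState",
    "NoReferenceError",
    "method1_heading",
    "dynamic_heading",
    "ExternalReferenceConfirmer",
    "confirm_external_reference",
    "compute_correction",
    "method2_heading",
    "Method2Fusion",
]


class NoReferenceError(RuntimeError):
    """Raised when a Method2 heading is requested before any external
    reference has been confirmed; the caller must withhold the heading."""


@dataclass
class HeadingState:
    """Method2 fusion state: the latched correction angle and bookkeeping."""

    delta_c: float | None = None
    last_theta: float | None = None
    reference_confirmed_at: float | None = None


def method1_heading(alpha: float, psi: float) -> float:
    """Person heading in the tracking frame from the device's
    North-referenced yaw, assuming the predetermined mounting
    (device y along the dorsoventral axis, delta = 0)."""
    return wrap_heading(alpha - psi + 90.0)


def dynamic_heading(t, x, y, min_speed: float = 0.3) -> float | None:
    """Heading of the track's velocity vector over a position window.

    The velocity is the least-squares linear fit of x(t), y(t); returns
    None when the speed is below ``min_speed`` (the velocity direction of
    a near-stationary track is noise).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        return None
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom <= 0:
        return None
    vx = float(tc @ (x - x.mean())) / denom
    vy = float(tc @ (y - y.mean())) / denom
    if np.hypot(vx, vy) < min_speed:
        return None
    return wrap_heading(np.degrees(np.arctan2(vy, vx)))


class ExternalReferenceConfirmer:
    """Confirms the static heading as the external reference theta_s when
    it stays within ``bound`` degrees of the dynamic heading for ``k``
    consecutive frames; missing values or violations reset the count."""

    def __init__(self, bound: float = 15.0, k: int = 3):
        self.bound = bound
        self.k = k
        self._run = 0

    def update(self, static_h: float | None, dynamic_h: float | None) -> float | None:
        if static_h is None or dynamic_h is None:
            self._run = 0
            return None
        if abs(signed_angle_diff(static_h, dynamic_h)) <= self.bound:
            self._run += 1
        else:
            self._run = 0
            return None
        if self._run >= self.k:
            self._run = 0
            return wrap_heading(static_h)
        return None


def confirm_external_reference(
    static_stream, dynamic_stream, bound: float = 15.0, k: int = 3
) -> float | None:
    """Run the confirmation rule over aligned static/dynamic streams and
    return the first confirmed theta_s, or None."""
    confirmer = ExternalReferenceConfirmer(bound, k)
    for s, d in zip(static_stream, dynamic_stream):
        theta_s = confirmer.update(s, d)
        if theta_s is not None:
            return theta_s
    return None


def compute_correction(theta_i: float, theta_s: float) -> float:
    """Correction angle delta_c between the inertially projected device
    axis angle and the freshly confirmed external reference."""
    return signed_angle_diff(theta_i, theta_s)


def method2_heading(theta_i: float, state: HeadingState) -> float:
    """Person heading from the projected device axis angle and the latched
    correction angle. Raises :class:`NoReferenceError` until the first
    reference has been confirmed."""
    if state.delta_c is None:
        raise NoReferenceError("no external heading reference confirmed yet")
    theta = wrap_heading(theta_i - state.delta_c)
    state.last_theta = theta
    return theta


class Method2Fusion:
    """Stateful Method2 pipeline: consistency-gated static heading plus
    dynamic heading confirm theta_s; delta_c is (re)latched at every new
    confirmation (latest wins, tolerating slow mount drift)."""

    def __init__(self, bound: float = 15.0, k: int = 3):
        self.state = HeadingState()
        self.confirmer = ExternalReferenceConfirmer(bound, k)

    def update(
        self,
        t: float,
        theta_i: float | None,
        static_h: float | None,
        dynamic_h: float | None,
    ) -> float | None:
        """Advance one tracker frame; returns the heading or None while no
        reference is available."""
        theta_s = self.confirmer.update(static_h, dynamic_h)
        if theta_s is not None and theta_i is not None:
            self.state.delta_c = compute_correction(theta_i, theta_s)
            self.state.reference_confirmed_at = t
        if self.state.delta_c is None or theta_i is None:
            return None
        return method2_heading(theta_i, self.state)
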