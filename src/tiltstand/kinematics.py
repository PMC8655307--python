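"""Sagittal marker kinematics: smoothing, CoM angle, segment rotations.

The body is a five-segment rigid-link chain (foot, leg, lower trunk, upper
trunk, head) defined on nine landmarks digitized on the right side of the
animal: the 4th metatarsophalangeal joint (``mtp``), lateral malleolus
(``ankle``), knee, greater trochanter (``hip``), iliac crest, the midpoint
between iliac crest and scapula (``mid_trunk``), scapula, temporomandibular
joint (``tmj``) and nose.  Coordinates are sagittal-plane meters with x
pointing forward (the facing direction) and y up; angles are measured from
the vertical with backward rotation positive.

Each segment carries an inertial description measured on frozen cadavers:
its mass as a percentage of body mass and its CoM location in the segment
frame, ``Ls`` percent along the lower-to-upper line and ``Lv`` percent
perpendicular to it.  Positive ``Lv`` displaces the segment CoM toward the
animal's ventral side (the facing direction when upright); the head's
negative ``Lv`` places its CoM dorsally.

The per-segment rotation-effect statistic E_i integrates, over a window
after tilt onset, the segment's angular velocity weighted by the mass of
the body part from that segment up and by the cosine of the angle between
the MTP-to-whole-body-CoM vector and the vector from the segment's lower
marker to the CoM of that upper body part.  It attributes CoM-angle change
to individual segment rotations under the assumption that the body above
the segment rotates rigidly about the segment's lower end.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "LANDMARKS",
    "SegmentSpec",
    "SegmentModel",
    "MarkerFrames",
    "smooth_markers",
    "whole_body_com",
    "com_angle",
    "segment_angles",
    "segment_angular_velocities",
    "segment_effect",
    "segment_effects",
]

LANDMARKS = (
    "mtp", "ankle", "knee", "hip", "iliac_crest",
    "mid_trunk", "scapula", "tmj", "nose",
)


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    mass_pct: float
    ls_pct: float
    lv_pct: float
    lower_marker: str
    upper_marker: str


@dataclass(frozen=True)
class SegmentModel:
    """Ordered (bottom to top) rigid segments with inertial fractions."""

    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_pct for s in self.segments)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"segment mass fractions must sum to 100, got {total}")
        for s in self.segments:
            for marker in (s.lower_marker, s.upper_marker):
                if marker not in LANDMARKS:
                    raise ValueError(f"unknown landmark {marker!r} in {s.name}")

    @classmethod
    def default(cls) -> "SegmentModel":
        """The packaged cadaver-measured inertial table."""
        path = resources.files("tiltstand.data") / "segment_inertia.csv"
        with path.open("r", newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            segments=tuple(
                SegmentSpec(
                    name=r["segment"],
                    mass_pct=float(r["mass_pct"]),
                    ls_pct=float(r["ls_pct"]),
                    lv_pct=float(r["lv_pct"]),
                    lower_marker=r["lower_marker"],
                    upper_marker=r["upper_marker"],
                )
                for r in rows
            )
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def index(self, segment) -> int:
        if isinstance(segment, str):
            return self.names.index(segment)
        return int(segment)

    def mass_above_pct(self, i: int) -> float:
        """Mass of the body part from segment ``i`` upward, % of body mass."""
        return sum(s.mass_pct for s in self.segments[i:])


@dataclass
class MarkerFrames:
    """Time series of the nine sagittal landmarks (meters)."""

    times: np.ndarray
    coords: dict

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        missing = [m for m in LANDMARKS if m not in self.coords]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        n = len(self.times)
        for name in LANDMARKS:
            arr = np.asarray(self.coords[name], dtype=float)
            if arr.shape != (n, 2):
                raise ValueError(f"landmark {name!r} must have shape ({n}, 2)")
            self.coords[name] = arr
        if n >= 2 and np.ptp(np.diff(self.times)) > 1e-9:
            raise ValueError("marker sampling must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def smooth_markers(
    frames: MarkerFrames, cutoff: float = 15.0, order: int = 4
) -> MarkerFrames:
    """Zero-phase Butterworth low-pass of every coordinate.

    Defaults to the 15 Hz 4th-order filter used on the motion-capture data;
    forward-backward application doubles the effective order and removes
    phase lag, so the attenuation is the squared magnitude response.
    """
    nyq = frames.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie below Nyquist {nyq} Hz")
    b, a = butter(order, cutoff / nyq)
    smoothed = {
        name: filtfilt(b, a, xy, axis=0) for name, xy in frames.coords.items()
    }
    return MarkerFrames(times=frames.times.copy(), coords=smoothed)


def _segment_vectors(frames: MarkerFrames, seg: SegmentSpec):
    p_lo = frames.coords[seg.lower_marker]
    p_hi = frames.coords[seg.upper_marker]
    u = p_hi - p_lo
    length = np.linalg.norm(u, axis=1)
    bad = np.nonzero(length == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"zero-length segment {seg.name!r} at frame {int(bad[0])}"
        )
    return p_lo, u, length


def _segment_com(frames: MarkerFrames, seg: SegmentSpec) -> np.ndarray:
    p_lo, u, length = _segment_vectors(frames, seg)
    # ventral normal: the segment line rotated -90 deg (forward for an
    # upright, forward-facing animal)
    normal = np.column_stack([u[:, 1], -u[:, 0]]) / length[:, None]
    return p_lo + (seg.ls_pct / 100.0) * u + (seg.lv_pct / 100.0) * (
        length[:, None] * normal
    )


def whole_body_com(frames: MarkerFrames, model: SegmentModel) -> np.ndarray:
    """Mass-fraction-weighted CoM of the five segments, per frame (n, 2)."""
    com = np.zeros_like(frames.coords["mtp"])
    for seg in model.segments:
        com += (seg.mass_pct / 100.0) * _segment_com(frames, seg)
    return com


def _angle_from_vertical(v: np.ndarray) -> np.ndarray:
    # backward (-x) lean positive
    return np.arctan2(-v[:, 0], v[:, 1])


def com_angle(frames: MarkerFrames, model: SegmentModel) -> np.ndarray:
    """Angle of the MTP-to-whole-body-CoM vector from vertical, rad."""
    return _angle_from_vertical(whole_body_com(frames, model) - frames.coords["mtp"])


def segment_angles(frames: MarkerFrames, model: SegmentModel) -> dict:
    """Per-segment line angle from vertical (backward positive), rad."""
    out = {}
    for seg in model.segments:
        _, u, _ = _segment_vectors(frames, seg)
        out[seg.name] = _angle_from_vertical(u)
    return out


def segment_angular_velocities(frames: MarkerFrames, model: SegmentModel) -> dict:
    """Segment angular velocities by central differences (one-sided at the
    edges), after unwrapping to avoid +/-pi jumps."""
    angles = segment_angles(frames, model)
    return {
        name: np.gradient(np.unwrap(a), frames.times) for name, a in angles.items()
    }


def _upper_part_com(frames: MarkerFrames, model: SegmentModel, i: int) -> np.ndarray:
    total = model.mass_above_pct(i)
    com = np.zeros_like(frames.coords["mtp"])
    for seg in model.segments[i:]:
        com += (seg.mass_pct / total) * _segment_com(frames, seg)
    return com


def segment_effect(
    frames: MarkerFrames,
    model: SegmentModel,
    segment,
    window: tuple[float, float] = (0.0, 0.3),
) -> float:
    """Rotation effect E_i of one segment on the CoM angle, degrees.

    Trapezoidal integration over ``window`` of
    (m_i/M) * cos(angle(r, r_i)) * omega_i, where m_i is the mass from
    segment ``i`` upward, r the MTP-to-whole-body-CoM vector, r_i the vector
    from the segment's lower marker to the CoM of the body part from the
    segment upward, and omega_i the segment's angular velocity.  The cosine
    is the signed normalized dot product.  Frames should be smoothed first.
    """
    t0, t1 = window
    eps = 1e-9
    if t0 < frames.times[0] - eps or t1 > frames.times[-1] + eps or t1 <= t0:
        raise ValueError(
            f"window {window} outside recording "
            f"[{frames.times[0]:.3f}, {frames.times[-1]:.3f}] s"
        )
    i = model.index(segment)
    seg = model.segments[i]
    omega = segment_angular_velocities(frames, model)[seg.name]
    r = whole_body_com(frames, model) - frames.coords["mtp"]
    r_i = _upper_part_com(frames, model, i) - frames.coords[seg.lower_marker]
    cos = np.einsum("ij,ij->i", r, r_i) / (
        np.linalg.norm(r, axis=1) * np.linalg.norm(r_i, axis=1)
    )
    integrand = (model.mass_above_pct(i) / 100.0) * cos * omega
    mask = (frames.times >= t0 - eps) & (frames.times <= t1 + eps)
    return float(np.degrees(np.trapezoid(integrand[mask], frames.times[mask])))


def segment_effects(
    frames: MarkerFrames,
    model: SegmentModel,
    window: tuple[float, float] = (0.0, 0.3),
) -> dict:
    """E_i for every segment, degrees."""
    return {
        seg.name: segment_effect(frames, model, i, window)
        for i, seg in enumerate(model.segments)
    }
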