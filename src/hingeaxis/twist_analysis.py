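"""Twist (screw) algebra and aggregation of sampled motions into an axis.

An instantaneous rigid-body motion is a twist ``(ω, v)``: ``ω`` is the
angular velocity (axis direction and rotation speed), ``v`` the
translational part, and a point ``p`` on the body moves with velocity
``p' = ω×p + v``. By Chasles' theorem every twist is a rotation plus a
translation along one line, the *twist axis*. The angle α between ω and v —
the *twist purity* — is 90° for a pure rotation (or translation) and drifts
away from 90° for general screw motions.

Aggregation over the sterically retained samples follows the published
recipe: the moving cluster's twists are averaged component-wise, the mean
twist is rescaled so its sixth component is 1, and the axis is reported as
the point on it closest to the origin plus that point offset by ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Twist",
    "AxisPrediction",
    "UndefinedPurityError",
    "purity",
    "point_velocity",
    "axis_from_twist",
    "mean_twist",
    "mean_purity",
    "predict_axis",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class Twist:
    """A twist stored as the 6-vector (ω₁, ω₂, ω₃, v₁, v₂, v₃)."""

    omega: tuple[float, float, float]
    v: tuple[float, float, float]

    def __post_init__(self) -> None:
        vec = np.concatenate([self.omega, self.v])
        if not np.all(np.isfinite(vec)):
            raise ValueError("twist components must be finite")

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "Twist":
        vec = np.asarray(vec, float)
        if vec.shape != (6,):
            raise ValueError("twist vector must have 6 components")
        return cls(omega=tuple(vec[:3]), v=tuple(vec[3:]))

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.omega, self.v])

    @property
    def is_pure_rotation(self) -> bool:
        """Zero translational part: rotation about a line through the origin."""
        return bool(np.linalg.norm(self.v) <= _ZERO_TOL)

    @property
    def is_pure_translation(self) -> bool:
        return bool(np.linalg.norm(self.omega) <= _ZERO_TOL)


class UndefinedPurityError(ValueError):
    """Purity is undefined for pure rotations through the origin (v = 0) or
    pure translations (ω = 0); ``kind`` distinguishes the two."""

    def __init__(self, kind: str):
        super().__init__(f"undefined purity: twist is a {kind}")
        self.kind = kind  # "pure rotation" | "pure translation"


def purity(twist: Twist) -> float:
    """Twist purity α = angle between ω and v, in degrees ∈ [0, 180]."""
    omega = np.asarray(twist.omega)
    v = np.asarray(twist.v)
    n_o, n_v = np.linalg.norm(omega), np.linalg.norm(v)
    if n_o <= _ZERO_TOL:
        raise UndefinedPurityError("pure translation")
    if n_v <= _ZERO_TOL:
        raise UndefinedPurityError("pure rotation")
    cosang = float(np.dot(omega, v) / (n_o * n_v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def point_velocity(twist: Twist, p: Sequence[float]) -> np.ndarray:
    """Velocity of a body point under the twist: p' = ω×p + v."""
    return np.cross(twist.omega, np.asarray(p, float)) + np.asarray(twist.v, float)


def axis_from_twist(twist: Twist, convention: str = "table") -> tuple[np.ndarray, np.ndarray]:
    """Two points on the twist axis: the closest-to-origin point and that
    point offset by ω (so the segment has the axis direction, length ‖ω‖).

    Two sign conventions coexist in the literature on these aggregated
    twists. ``convention="table"`` computes ``(v×ω)/‖ω‖²`` — the form in
    which published mean-twist axis points are reported. For a twist whose
    point velocities follow ``p' = ω×p + v``, however, the actual axis of
    rotation passes through ``(ω×v)/‖ω‖²`` (``convention="kinematic"``);
    the two points are reflections of each other through the origin. Use
    "table" to compare against published values and "kinematic" when the
    axis is drawn against the structure.
    """
    omega = np.asarray(twist.omega, float)
    norm2 = float(np.dot(omega, omega))
    if norm2 <= _ZERO_TOL**2:
        raise ValueError("pure translation; no rotation axis")
    if convention == "table":
        p1 = np.cross(twist.v, omega) / norm2
    elif convention == "kinematic":
        p1 = np.cross(omega, twist.v) / norm2
    else:
        raise ValueError("convention must be 'table' or 'kinematic'")
    return p1, p1 + omega


@dataclass
class AxisPrediction:
    """Aggregated motion of the moving cluster relative to the pinned one."""

    mean_twist: Twist  # sixth component normalized to 1 when possible
    mean_twist_raw: Twist  # plain component-wise average
    mean_purity: float  # degrees; mean of per-sample purities
    axis_point: tuple[float, float, float]  # closest point to origin (kinematic)
    axis_point_2: tuple[float, float, float]  # axis_point + ω
    pinned_cluster: int
    moving_cluster: int
    n_samples_used: int
    axis_point_table: tuple[float, float, float] = (0.0, 0.0, 0.0)  # published convention
    axis_point_2_table: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_purity_undefined: int = 0
    normalized: bool = True

    def as_dict(self) -> dict:
        return {
            "mean_twist": [float(x) for x in self.mean_twist.vector],
            "mean_twist_raw": [float(x) for x in self.mean_twist_raw.vector],
            "mean_twist_normalized": self.normalized,
            "mean_purity_deg": float(self.mean_purity),
            "axis_point": [float(x) for x in self.axis_point],
            "axis_point_2": [float(x) for x in self.axis_point_2],
            "axis_point_table_convention": [float(x) for x in self.axis_point_table],
            "axis_point_2_table_convention": [float(x) for x in self.axis_point_2_table],
            "pinned_cluster": self.pinned_cluster,
            "moving_cluster": self.moving_cluster,
            "n_samples_used": self.n_samples_used,
            "n_purity_undefined": self.n_purity_undefined,
        }


def _moving_twists(samples: Sequence, moving_cluster: int) -> list[Twist]:
    if not samples:
        raise ValueError("no retained samples to aggregate")
    return [s.per_body_twists[moving_cluster] for s in samples]


def mean_twist(
    samples: Sequence,
    moving_cluster: int,
    normalize: bool = True,
    per_sample_normalize: bool = False,
) -> tuple[Twist, Twist, bool]:
    """Component-wise mean of the moving cluster's twists over samples.

    Returns ``(normalized, raw, was_normalized)``. Normalization divides by
    the sixth component (v₃) when its magnitude exceeds 1e-9, the convention
    in which aggregated twists are reported; otherwise the raw mean is
    returned unscaled with a flag. ``per_sample_normalize`` rescales each
    sample twist before averaging instead (alternative aggregation, off by
    default).
    """
    twists = _moving_twists(samples, moving_cluster)
    vecs = np.array([t.vector for t in twists])
    if per_sample_normalize:
        scaled = []
        for row in vecs:
            scaled.append(row / row[5] if abs(row[5]) > 1e-9 else row)
        vecs = np.array(scaled)
    raw = vecs.mean(axis=0)
    raw_twist = Twist.from_vector(raw)
    if abs(raw[5]) > 1e-9:
        return Twist.from_vector(raw / raw[5]), raw_twist, True
    import logging

    logging.getLogger(__name__).warning(
        "mean twist has near-zero sixth component; normalization skipped"
    )
    return raw_twist, raw_twist, False


def mean_purity(samples: Sequence, moving_cluster: int) -> tuple[float, int]:
    """Arithmetic mean of per-sample purities; returns (mean, n_undefined).

    Samples whose moving-cluster twist has zero ω or zero v are excluded
    from the mean and counted.
    """
    values = []
    undefined = 0
    for t in _moving_twists(samples, moving_cluster):
        try:
            values.append(purity(t))
        except UndefinedPurityError:
            undefined += 1
    if not values:
        raise ValueError("purity undefined for every retained sample")
    return float(np.mean(values)), undefined


def predict_axis(
    samples: Sequence,
    moving_cluster: int,
    pinned_cluster: int,
    per_sample_normalize: bool = False,
) -> AxisPrediction:
    """Aggregate retained samples into the predicted axis of motion.

    The geometric axis (``axis_point``/``axis_point_2``) uses the kinematic
    convention, i.e. it is the actual line about which the moving cluster
    rotates under the mean twist; the table-convention point pair is also
    carried for comparison with published aggregated twists.
    """
    mt, raw, normalized = mean_twist(
        samples, moving_cluster, per_sample_normalize=per_sample_normalize
    )
    mp, undefined = mean_purity(samples, moving_cluster)
    p1, p2 = axis_from_twist(mt, convention="kinematic")
    t1, t2 = axis_from_twist(mt, convention="table")
    return AxisPrediction(
        mean_twist=mt,
        mean_twist_raw=raw,
        mean_purity=mp,
        axis_point=tuple(float(x) for x in p1),
        axis_point_2=tuple(float(x) for x in p2),
        axis_point_table=tuple(float(x) for x in t1),
        axis_point_2_table=tuple(float(x) for x in t2),
        pinned_cluster=pinned_cluster,
        moving_cluster=moving_cluster,
        n_samples_used=len(samples),
        n_purity_undefined=undefined,
        normalized=normalized,
    )
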