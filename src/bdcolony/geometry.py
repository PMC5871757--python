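"""Planar spherocylinder geometry.

A cell is a spherocylinder: a cylinder (axis segment) of length ``L`` capped
by two hemispherical ends of diameter ``sigma``, so the tip-to-tip length is
``L + sigma`` and the aspect ratio is ``L* = (L + sigma)/sigma``.  All lengths
are expressed in units of the (constant) diameter ``sigma``, all angles in
radians.  The orientation is stored as an angle ``theta`` with unit vector
``e = (cos theta, sin theta)``; the particles are apolar (``e`` and ``-e``
describe the same cell).

This module provides the exact segment-segment and point-segment distance
primitives that both the pair-force evaluation and the Monte-Carlo coverage
estimator are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spherocylinder",
    "ClusterState",
    "closest_approach",
    "point_covered",
    "center_of_mass",
]

_PARALLEL_EPS = 1e-12


@dataclass
class Spherocylinder:
    """One rod-shaped cell.

    Parameters
    ----------
    center : (2,) array_like
        Position of the geometric center, sigma units.
    theta : float
        Orientation angle in radians; orientation vector is
        ``(cos theta, sin theta)``.
    cyl_length : float
        Length ``L`` of the cylindrical section (axis segment), sigma units.
        Tip-to-tip length is ``L + diameter``.
    diameter : float
        Cell width ``sigma``; 1 in reduced units.
    """

    center: np.ndarray
    theta: float
    cyl_length: float
    diameter: float = 1.0
    id: int = 0
    parent_id: int | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        if self.cyl_length < 0:
            raise ValueError("cyl_length must be >= 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")

    @property
    def orientation(self) -> np.ndarray:
        """Unit orientation vector e = (cos theta, sin theta)."""
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    @property
    def aspect_ratio(self) -> float:
        """L* = (L + sigma) / sigma."""
        return (self.cyl_length + self.diameter) / self.diameter

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """The two ends of the axis segment (not the hemispherical tips)."""
        h = 0.5 * self.cyl_length * self.orientation
        return self.center - h, self.center + h


@dataclass
class ClusterState:
    """A colony snapshot: particle collection plus the simulation clock.

    Growth is deterministic and synchronized (all cells are born at the same
    length and elongate at the same velocity), so divisions happen in rounds
    and the particle count is always ``2**division_rounds``.
    """

    particles: list[Spherocylinder] = field(default_factory=list)
    time: float = 0.0
    division_rounds: int = 0

    def __len__(self) -> int:
        return len(self.particles)

    # -- array views used by the morphometrics and the engine ---------------

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.particles], dtype=float).reshape(-1, 2)

    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.particles], dtype=float)

    def cyl_lengths(self) -> np.ndarray:
        return np.array([p.cyl_length for p in self.particles], dtype=float)

    def validate(self) -> None:
        if len(self.particles) != 2 ** self.division_rounds:
            raise ValueError(
                f"particle count {len(self.particles)} != 2**division_rounds"
            )
        ids = [p.id for p in self.particles]
        if len(set(ids)) != len(ids):
            raise ValueError("particle ids are not unique")


def _segment_params(p: Spherocylinder) -> tuple[np.ndarray, np.ndarray, float]:
    return p.center, p.orientation, 0.5 * p.cyl_length


def closest_approach(
    a: Spherocylinder, b: Spherocylinder
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between the axis segments of two spherocylinders.

    Returns ``(d_m, p_a, p_b)`` where ``p_a`` and ``p_b`` are the closest
    points on the axis of ``a`` and ``b`` respectively and
    ``d_m = |p_a - p_b|``.  Uses exact clamped minimization over the two
    segment parameters (Vega-Lago style).  When the minimizer is non-unique
    (parallel overlapping spans) the tie is broken at the midpoint of the
    overlap interval, which keeps the torque of a perfectly parallel aligned
    pair exactly zero.
    """
    ca, ea, ha = _segment_params(a)
    cb, eb, hb = _segment_params(b)
    s, t = _closest_segment_params(ca, ea, ha, cb, eb, hb)
    p_a = ca + s * ea
    p_b = cb + t * eb
    return float(np.linalg.norm(p_a - p_b)), p_a, p_b


def _closest_segment_params(ca, ea, ha, cb, eb, hb) -> tuple[float, float]:
    """Segment parameters (s, t) in [-ha, ha] x [-hb, hb] minimizing distance."""
    r = ca - cb
    bdot = float(ea @ eb)
    f = float(eb @ r)
    c = float(ea @ r)
    denom = 1.0 - bdot * bdot

    if ha == 0.0 and hb == 0.0:
        return 0.0, 0.0
    if ha == 0.0:
        return 0.0, float(np.clip(f, -hb, hb))
    if hb == 0.0:
        return float(np.clip(-c, -ha, ha)), 0.0

    if denom > _PARALLEL_EPS:
        s = (bdot * f - c) / denom
        s = float(np.clip(s, -ha, ha))
        t = bdot * s + f
        if t < -hb or t > hb:
            t = float(np.clip(t, -hb, hb))
            s = float(np.clip(bdot * t - c, -ha, ha))
        return s, float(t)

    # Parallel axes: the projection of segment b onto the axis of a spans
    # [proj - hb, proj + hb] (bdot = +-1).  Overlap with [-ha, ha] gives a
    # continuum of minimizers; take its midpoint.
    proj = -c  # parameter on a closest to b's center
    lo = max(-ha, proj - hb)
    hi = min(ha, proj + hb)
    if lo <= hi:
        s = 0.5 * (lo + hi)
    else:
        s = -ha if proj < 0 else ha
    t = float(np.clip(bdot * s + f, -hb, hb))
    return float(s), t


def point_covered(pt: np.ndarray, p: Spherocylinder) -> bool:
    """True iff ``pt`` lies inside (or on) the spherocylinder footprint.

    The footprint is the set of points within ``sigma/2`` of the axis
    segment; the boundary counts as covered (closed-set convention).
    """
    return _point_segment_distance(np.asarray(pt, float), p) <= 0.5 * p.diameter


def _point_segment_distance(pt: np.ndarray, p: Spherocylinder) -> float:
    c, e, h = _segment_params(p)
    t = float(np.clip((pt - c) @ e, -h, h))
    return float(np.linalg.norm(pt - (c + t * e)))


def center_of_mass(c: ClusterState) -> np.ndarray:
    """Unweighted mean of particle centers (one unit point mass per cell)."""
    if len(c.particles) == 0:
        raise ValueError("center of mass of an empty cluster is undefined")
    return c.centers().mean(axis=0)
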