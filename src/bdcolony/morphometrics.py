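"""Cluster-scale descriptors of colony shape, coverage and order.

Three quantities characterize a microcolony:

* the radial coverage profile ``g(r)`` — the fraction of annulus area at
  distance r from the colony center of mass that is covered by cells,
  estimated by Monte-Carlo point sampling;
* the eccentricity ``Phi = sqrt(1 - I'x/I'y)`` from the eigenvalues
  (I'x <= I'y) of the inertia tensor of the particle centers — 0 for a
  circular colony, approaching 1 for an elongated one;
* the 2-D nematic order parameter ``S2`` — the largest eigenvalue of the
  traceless orientation tensor Q = <2 e e - 1> — 0 for random orientations,
  1 for perfect alignment (apolar: e and -e are equivalent).

Cells contribute to g(r) with their full spherocylinder footprint, and to
the inertia and orientation tensors as unit point masses / unit directors at
their centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ClusterState, center_of_mass

__all__ = [
    "CoverageProfile",
    "MorphometricsRecord",
    "coverage_profile",
    "major_radius",
    "inertia_tensor",
    "eccentricity",
    "nematic_order",
    "morphometrics_record",
    "replicate_summary",
]


@dataclass
class CoverageProfile:
    """Radial coverage table g(r) for one colony snapshot."""

    r_edges: np.ndarray  # annulus edges, strictly increasing, sigma units
    g_values: np.ndarray  # covered-area fraction per annulus, in [0, 1]
    n_points: int  # MC sample points per annulus
    center: np.ndarray  # the center of mass used

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, float)
        self.g_values = np.asarray(self.g_values, float)
        if len(self.r_edges) != len(self.g_values) + 1:
            raise ValueError("need len(r_edges) == len(g_values) + 1")
        if np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("r_edges must be strictly increasing")
        if np.any((self.g_values < 0) | (self.g_values > 1)):
            raise ValueError("g values must lie in [0, 1]")

    def central_mean(self, r_max: float = 2.0) -> float:
        """Mean g over the annuli whose outer edge is <= r_max."""
        mask = self.r_edges[1:] <= r_max + 1e-12
        if not mask.any():
            raise ValueError(f"no annulus with outer edge <= {r_max}")
        return float(self.g_values[mask].mean())


@dataclass
class MorphometricsRecord:
    """Shape/order summary of one snapshot (optionally replicate-averaged)."""

    n_particles: int
    S2: float
    Phi: float
    major_radius: float


def _point_in_any(points: np.ndarray, centers, ex, ey, half_len) -> np.ndarray:
    """Vectorized covered test: distance to any axis segment <= 1/2."""
    # points (M,2); segments (N,)
    dx = points[:, 0, None] - centers[None, :, 0]
    dy = points[:, 1, None] - centers[None, :, 1]
    t = dx * ex[None, :] + dy * ey[None, :]
    t = np.clip(t, -half_len[None, :], half_len[None, :])
    qx = dx - t * ex[None, :]
    qy = dy - t * ey[None, :]
    return ((qx * qx + qy * qy) <= 0.25 + 1e-15).any(axis=1)


def coverage_profile(
    c: ClusterState,
    dr: float = 0.5,
    n_points: int = 10_000,
    rng: np.random.Generator | None = None,
    *,
    covered_test=None,
) -> CoverageProfile:
    """Monte-Carlo coverage profile around the cluster center of mass.

    For each annulus [k dr, (k+1) dr) the estimate is the fraction of
    ``n_points`` points, drawn uniformly by area within the annulus, that
    fall inside at least one cell.  Annuli extend one bin past the largest
    possible cell extent, so the profile always ends in a zero bin.

    ``covered_test`` is a test hook replacing the geometric point-in-particle
    predicate (signature ``f(points) -> bool array``).
    """
    if len(c) == 0:
        raise ValueError("coverage profile of an empty cluster")
    if dr <= 0 or n_points < 1:
        raise ValueError("dr must be > 0 and n_points >= 1")
    rng = np.random.default_rng() if rng is None else rng
    com = center_of_mass(c)

    centers = c.centers() - com
    th = c.thetas()
    ex, ey = np.cos(th), np.sin(th)
    half_len = 0.5 * c.cyl_lengths()
    extent = float(np.max(np.hypot(centers[:, 0], centers[:, 1]) + half_len + 0.5))
    n_bins = int(np.ceil(extent / dr)) + 1

    edges = dr * np.arange(n_bins + 1)
    g = np.empty(n_bins)
    for k in range(n_bins):
        r1, r2 = edges[k], edges[k + 1]
        u = rng.random(n_points)
        r = np.sqrt(r1 * r1 + u * (r2 * r2 - r1 * r1))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_points)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        if covered_test is not None:
            inside = np.asarray(covered_test(pts + com), bool)
        else:
            inside = _point_in_any(pts, centers, ex, ey, half_len)
        g[k] = inside.mean()
    return CoverageProfile(r_edges=edges, g_values=g, n_points=n_points, center=com)


def major_radius(p: CoverageProfile) -> float:
    """Outer edge of the last annulus with g > 0; 0 if the profile is empty."""
    nz = np.nonzero(p.g_values > 0)[0]
    if len(nz) == 0:
        return 0.0
    return float(p.r_edges[nz[-1] + 1])


def inertia_tensor(c: ClusterState) -> np.ndarray:
    """Planar inertia tensor of the particle centers about the center of mass.

    I_ij = (1/N) sum_k [delta_ij |r_k|^2 - r_k,i r_k,j] with each cell one
    unit point mass at its center; symmetric positive semidefinite.
    """
    r = c.centers() - center_of_mass(c)
    n = len(r)
    r2 = (r**2).sum(axis=1)
    I = np.eye(2) * r2.mean() - (r[:, :, None] * r[:, None, :]).mean(axis=0)
    return I


def eccentricity(c: ClusterState) -> float:
    """Phi = sqrt(1 - lambda_min/lambda_max) of the inertia tensor.

    0 for a circularly symmetric arrangement, 1 for perfectly collinear
    centers.  Undefined (raises) when all centers coincide.
    """
    lam = np.linalg.eigvalsh(inertia_tensor(c))
    lam_min, lam_max = float(lam[0]), float(lam[1])
    if lam_max <= 0:
        raise ValueError("eccentricity undefined: all particle centers coincide")
    ratio = max(lam_min, 0.0) / lam_max
    return float(np.sqrt(max(0.0, 1.0 - ratio)))


def nematic_order(c: ClusterState) -> float:
    """2-D nematic order parameter S2.

    Largest eigenvalue of the traceless apolar orientation tensor
    Q = (1/N) sum_i (2 e_i e_i - 1).  Equals the maximum over director
    angles of <cos 2(theta_i - theta_dir)>: 0 in the isotropic limit,
    1 when all cells share one (apolar) orientation.
    """
    if len(c) == 0:
        raise ValueError("nematic order of an empty cluster")
    th = c.thetas()
    # Q = [[<cos 2t>, <sin 2t>], [<sin 2t>, -<cos 2t>]]; top eigenvalue is
    # the modulus of the mean 2theta phasor
    return float(np.hypot(np.cos(2 * th).mean(), np.sin(2 * th).mean()))


def morphometrics_record(
    c: ClusterState,
    dr: float = 0.5,
    n_points: int = 10_000,
    rng: np.random.Generator | None = None,
) -> MorphometricsRecord:
    """Convenience bundle: S2, Phi and major radius for one snapshot."""
    prof = coverage_profile(c, dr=dr, n_points=n_points, rng=rng)
    return MorphometricsRecord(
        n_particles=len(c),
        S2=nematic_order(c),
        Phi=eccentricity(c),
        major_radius=major_radius(prof),
    )


def replicate_summary(records):
    """Mean and spread over replicate runs started from different seeds.

    For :class:`MorphometricsRecord` inputs returns a dict mapping each
    quantity (S2, Phi, major_radius) to (mean, sd, sem); for
    :class:`CoverageProfile` inputs returns (r_edges, mean g, sd g, sem g)
    per bin.  sd is the sample standard deviation (ddof=1); sem the standard
    deviation of the mean.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("replicate summary needs at least 2 replicates")
    if isinstance(records[0], CoverageProfile):
        edges = records[0].r_edges
        # profiles of different extents share the common inner bins; pad the
        # shorter ones with zeros (beyond a profile's last bin g is 0)
        n_bins = max(len(p.g_values) for p in records)
        longest = max(records, key=lambda p: len(p.g_values))
        for p in records:
            k = len(p.g_values)
            if not np.allclose(p.r_edges, longest.r_edges[: k + 1]):
                raise ValueError("replicate profiles have mismatched bin edges")
        G = np.zeros((len(records), n_bins))
        for i, p in enumerate(records):
            G[i, : len(p.g_values)] = p.g_values
        mean = G.mean(axis=0)
        sd = G.std(axis=0, ddof=1)
        return {
            "r_edges": longest.r_edges,
            "g_mean": mean,
            "g_sd": sd,
            "g_sem": sd / np.sqrt(len(records)),
        }
    out = {}
    for name in ("S2", "Phi", "major_radius"):
        vals = np.array([getattr(r, name) for r in records], float)
        sd = vals.std(ddof=1)
        out[name] = (float(vals.mean()), float(sd), float(sd / np.sqrt(len(vals))))
    return out
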