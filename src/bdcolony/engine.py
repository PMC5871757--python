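"""Brownian-dynamics engine for growing, dividing spherocylinder colonies.

The model: a single newborn rod of aspect ratio ``L*_0`` is seeded at the
origin; every cell elongates at a constant velocity ``v_gr`` and splits
transversally into two newborns when its aspect ratio reaches ``2 L*_0``.
Between divisions the cells move by overdamped Brownian dynamics in the
plane, with anisotropic translational diffusion (fast along the rod axis,
slow across it), rotational diffusion, and purely repulsive excluded-volume
pair forces (a WCA-type potential acting on the closest-approach distance
between the rod axes).

The single control parameter is the growth/diffusion competition ratio

    Gamma = t_dif / t_gr,
    t_dif = 0.25 sigma^2 / (D_par + D_perp)   (evaluated at L*_0),
    t_gr  = (L_0 + sigma) / v_gr,

so large Gamma means cells divide before they can diffuse away (compact,
"closed" growth) and small Gamma the opposite ("open" growth).  The engine
fixes the diffusional scale ``D0`` and calibrates ``v_gr`` to reach the
requested Gamma.

Reduced units throughout: sigma = kBT = 1; the time unit is
``tau = sigma^2 / D0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import ClusterState, Spherocylinder, closest_approach

__all__ = [
    "SimulationParams",
    "DiffusionCoefficients",
    "diffusion_coefficients",
    "calibrate_growth_velocity",
    "srs_potential",
    "pair_force_torque",
    "bd_step",
    "grow_and_divide",
    "run_simulation",
    "SimulationDiagnostics",
    "CUTOFF",
]

#: WCA cutoff on the closest-approach distance (sigma units)
CUTOFF = _kernels.CUTOFF
#: overlap guard: closest-approach distance is clamped to this inside the
#: force law so that division-induced transient contacts stay integrable
MIN_SEPARATION = _kernels.MIN_SEP

_DEFAULT_SNAPSHOTS = (32, 64, 128, 256, 512, 1024)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set of one simulation, in reduced units.

    Defaults are the conditions of the reference study: ``L*_0 = 2.6``
    (the initial aspect ratio measured for P. putida), ``D0 = 0.1``,
    ``dt* = 1e-4`` (time step over ``tau = sigma^2/D0``), snapshots at
    power-of-two colony sizes 32..1024, ten replicate seeds.
    """

    Gamma: float
    L_star_0: float = 2.6
    D0: float = 0.1
    dt_star: float = 1e-4
    epsilon: float = 1.0
    kBT: float = 1.0
    N_max: int = 1024
    snapshot_counts: tuple[int, ...] = _DEFAULT_SNAPSHOTS
    seed: int = 0
    replicates: int = 10
    mc_points_per_annulus: int = 10_000
    dr: float = 0.5

    def __post_init__(self):
        if not (self.Gamma > 0 and math.isfinite(self.Gamma)):
            raise ValueError(f"Gamma must be positive and finite, got {self.Gamma}")
        if self.L_star_0 <= 1:
            raise ValueError("L_star_0 must exceed 1 (a rod longer than wide)")
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        if self.dt_star <= 0:
            raise ValueError("dt_star must be positive")
        if self.epsilon <= 0 or self.kBT <= 0:
            raise ValueError("epsilon and kBT must be positive")
        if not _is_power_of_two(self.N_max):
            raise ValueError("N_max must be a power of 2 (synchronous doubling)")
        counts = tuple(sorted(int(c) for c in self.snapshot_counts))
        object.__setattr__(self, "snapshot_counts", counts)
        for c in counts:
            if not _is_power_of_two(c):
                raise ValueError(
                    f"snapshot count {c} is unreachable: divisions are "
                    "synchronized, so colony sizes are powers of 2"
                )
            if c > self.N_max:
                raise ValueError(f"snapshot count {c} exceeds N_max={self.N_max}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mc_points_per_annulus < 1 or self.dr <= 0:
            raise ValueError("invalid coverage-profile sampling parameters")

    # -- derived quantities -------------------------------------------------

    @property
    def sigma(self) -> float:
        return 1.0

    @property
    def L0(self) -> float:
        """Newborn cylinder length L_0 = (L*_0 - 1) sigma."""
        return (self.L_star_0 - 1.0) * self.sigma

    @property
    def tau(self) -> float:
        """Reduced time unit.

        Lengths are in sigma and D0 is quoted as a dimensionless diffusional
        scale (0.1 by default), so the unit of time is the one in which a
        particle with D = 1 diffuses sigma^2 per unit time: tau = 1.  The
        time step dt_star is expressed in this unit, giving a diffusion per
        step of order D0 * dt_star * sigma^2 (1e-5 at the defaults), which
        keeps the stiff excluded-volume forces of large dense colonies
        integrable with the explicit update.
        """
        return 1.0

    @property
    def dt(self) -> float:
        """Time step in absolute reduced-time units."""
        return self.dt_star * self.tau

    @property
    def v_gr(self) -> float:
        return calibrate_growth_velocity(self)


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Anisotropic rod diffusion coefficients (sigma^2/time, rad^2/time)."""

    D_par: float
    D_perp: float
    D_theta: float


def diffusion_coefficients(L_star: float, D0: float) -> DiffusionCoefficients:
    """Analytic rod diffusion coefficients at aspect ratio ``L_star``.

    Uses the Tirado-Garcia de la Torre end-corrected closed forms for a rod
    of length ``p = L_star`` diameters:

        D_par   = D0 (ln p + nu_par) / (2 p)
        D_perp  = D0 (ln p + nu_perp) / (4 p)
        D_theta = 3 D0 (ln p + nu_rot) / p^3

    with the published end-correction polynomials nu(p).  ``D0`` sets the
    overall diffusional scale (it absorbs temperature, medium viscosity and
    the cell-surface adhesion strength).
    """
    if not L_star >= 1.0:
        raise ValueError(f"aspect ratio must be >= 1, got {L_star}")
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    d_par, d_perp, d_rot = _kernels.rod_diffusion(float(L_star), float(D0))
    return DiffusionCoefficients(D_par=d_par, D_perp=d_perp, D_theta=d_rot)


def calibrate_growth_velocity(params: SimulationParams) -> float:
    """Elongation velocity giving the requested Gamma.

    Inverts Gamma = t_dif / t_gr with t_dif = 0.25 sigma^2 / (D_par + D_perp)
    evaluated at the constant newborn aspect ratio L*_0, and
    t_gr = (L_0 + sigma) / v_gr:

        v_gr = (L_0 + sigma) * Gamma * (D_par + D_perp) / (0.25 sigma^2)
    """
    c = diffusion_coefficients(params.L_star_0, params.D0)
    t_dif = 0.25 * params.sigma**2 / (c.D_par + c.D_perp)
    return (params.L0 + params.sigma) * params.Gamma / t_dif


def gamma_from_velocity(params: SimulationParams, v_gr: float) -> float:
    """Inverse of :func:`calibrate_growth_velocity` (round-trip check)."""
    c = diffusion_coefficients(params.L_star_0, params.D0)
    t_dif = 0.25 * params.sigma**2 / (c.D_par + c.D_perp)
    t_gr = (params.L0 + params.sigma) / v_gr
    return t_dif / t_gr


def srs_potential(d_m: float, epsilon: float = 1.0, sigma: float = 1.0) -> float:
    """Soft repulsive spherocylinder pair energy at closest approach ``d_m``.

    Truncated-shifted 12-6 (WCA) form acting on the minimum distance between
    the two axis segments:

        U(d) = 4 eps [(sigma/d)^12 - (sigma/d)^6] + eps   for d < 2^(1/6) sigma
        U(d) = 0                                          otherwise

    Purely repulsive: soft at small overlap, divergent at deep overlap.  To
    keep explicit integration stable, separations below 0.2 sigma are clamped
    (with a warning) before evaluating the divergence.
    """
    if d_m < 0:
        raise ValueError("d_m must be non-negative")
    if d_m >= CUTOFF * sigma:
        return 0.0
    if d_m < MIN_SEPARATION * sigma:
        warnings.warn(
            f"closest approach {d_m:.3g} below overlap guard; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        d_m = MIN_SEPARATION * sigma
    sr6 = (sigma / d_m) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon


def pair_force_torque(
    a: Spherocylinder, b: Spherocylinder, epsilon: float = 1.0
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """SRS force and torque on each particle of a pair.

    The force acts along the unit vector joining the closest points of the
    two axes, with magnitude -dU/dd of :func:`srs_potential`; the torque is
    the z-component of (contact point - center) x F.  Newton's third law
    holds exactly by construction.
    """
    d, p_a, p_b = closest_approach(a, b)
    if d >= CUTOFF:
        return np.zeros(2), 0.0, np.zeros(2), 0.0
    if d < MIN_SEPARATION:
        n = p_a - p_b
        nn = np.linalg.norm(n)
        if nn > 1e-12:
            n = n / nn
        else:
            cc = a.center - b.center
            cn = np.linalg.norm(cc)
            n = cc / cn if cn > 1e-12 else np.array([1.0, 0.0])
        d_eff = MIN_SEPARATION
    else:
        n = (p_a - p_b) / d
        d_eff = d
    inv6 = d_eff**-6
    fmag = 24.0 * epsilon * (2.0 * inv6 - 1.0) * inv6 / d_eff
    F_a = fmag * n
    F_b = -F_a
    r_a = p_a - a.center
    r_b = p_b - b.center
    T_a = float(r_a[0] * F_a[1] - r_a[1] * F_a[0])
    T_b = float(r_b[0] * F_b[1] - r_b[1] * F_b[0])
    return F_a, T_a, F_b, T_b


def total_forces(state: ClusterState, epsilon: float = 1.0):
    """Sum of SRS forces and torques over all pairs (reference path)."""
    n = len(state)
    F = np.zeros((n, 2))
    T = np.zeros(n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            fa, ta, fb, tb = pair_force_torque(
                state.particles[i], state.particles[j], epsilon
            )
            F[i] += fa
            T[i] += ta
            F[j] += fb
            T[j] += tb
    return F, T


def bd_step(
    state: ClusterState,
    params: SimulationParams,
    coeffs: list[DiffusionCoefficients],
    forces: np.ndarray,
    torques: np.ndarray,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
) -> ClusterState:
    """One overdamped Brownian-dynamics step (positions and orientations).

    For each particle the position update is decomposed along the rod axis
    ``e`` (mobility ``D_par``) and its normal ``u`` (mobility ``D_perp``)::

        dr = [D_par  F.e dt / kBT + sqrt(2 D_par  dt) R_par ] e
           + [D_perp F.u dt / kBT + sqrt(2 D_perp dt) R_perp] u
        dtheta = D_theta T dt / kBT + sqrt(2 D_theta dt) R_theta

    with independent standard gaussians R.  ``noise`` (shape (N, 3)) can be
    supplied explicitly — e.g. zeros — instead of drawing from ``rng``; this
    is the deterministic test hook.
    """
    n = len(state)
    if noise is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit noise array")
        noise = rng.standard_normal((n, 3))
    noise = np.asarray(noise, float).reshape(n, 3)
    dt = params.dt
    new_particles = []
    for i, p in enumerate(state.particles):
        c = coeffs[i]
        e = p.orientation
        u = np.array([-e[1], e[0]])
        fpar = float(forces[i] @ e)
        fperp = float(forces[i] @ u)
        dpar = c.D_par * fpar * dt / params.kBT + math.sqrt(2 * c.D_par * dt) * noise[i, 0]
        dperp = c.D_perp * fperp * dt / params.kBT + math.sqrt(2 * c.D_perp * dt) * noise[i, 1]
        dtheta = c.D_theta * float(torques[i]) * dt / params.kBT + math.sqrt(
            2 * c.D_theta * dt
        ) * noise[i, 2]
        new_particles.append(
            replace(p, center=p.center + dpar * e + dperp * u, theta=p.theta + dtheta)
        )
    return ClusterState(
        particles=new_particles,
        time=state.time + dt,
        division_rounds=state.division_rounds,
    )


def grow_and_divide(
    state: ClusterState,
    v_gr: float,
    dt: float,
    L_star_0: float,
    next_id: int | None = None,
) -> ClusterState:
    """Elongate every cell by ``v_gr dt`` and split those at the threshold.

    A cell whose aspect ratio reaches ``2 L*_0`` is replaced by two newborns
    of cylinder length ``L_0``, with the parent's orientation and centers at
    ``r_0 +/- 0.5 (L_0 + sigma) e`` — the daughters' joint footprint equals
    the parent's at the division instant.
    """
    L0 = (L_star_0 - 1.0)
    threshold = 2.0 * L0 + 1.0  # cylinder length at aspect ratio 2 L*_0
    if next_id is None:
        next_id = max((p.id for p in state.particles), default=-1) + 1
    grown = [replace(p, cyl_length=p.cyl_length + v_gr * dt) for p in state.particles]
    any_division = any(p.cyl_length >= threshold - 1e-12 for p in grown)
    if not any_division:
        return ClusterState(
            particles=grown, time=state.time, division_rounds=state.division_rounds
        )
    out: list[Spherocylinder] = []
    for p in grown:
        if p.cyl_length >= threshold - 1e-12:
            offset = 0.5 * (L0 + 1.0) * p.orientation
            for sign in (+1.0, -1.0):
                out.append(
                    Spherocylinder(
                        center=p.center + sign * offset,
                        theta=p.theta,
                        cyl_length=L0,
                        id=next_id,
                        parent_id=p.id,
                    )
                )
                next_id += 1
        else:
            out.append(p)
    return ClusterState(
        particles=out,
        time=state.time,
        division_rounds=state.division_rounds + 1,
    )


@dataclass
class SimulationDiagnostics:
    """Counters reported by :func:`run_simulation`."""

    n_clamped_contacts: int = 0
    n_deep_overlaps: int = 0
    n_steps: int = 0


# target bytes for one block of pre-drawn gaussian noise
_NOISE_BLOCK_BYTES = 48_000_000


def run_simulation(
    params: SimulationParams,
    diagnostics: SimulationDiagnostics | None = None,
) -> list[ClusterState]:
    """Grow a colony from one newborn cell; return the scheduled snapshots.

    One newborn of aspect ratio ``L*_0`` starts at the origin with a uniform
    random orientation in [0, pi).  Each step applies pair forces, the BD
    move, and elongation; when the synchronized division round fires, a
    snapshot is recorded immediately (before any further BD step) if the new
    colony size is on the schedule.  The run stops at ``N_max`` particles.

    Fully reproducible: the trajectory is a pure function of ``params``
    (including ``seed``).  Pass a :class:`SimulationDiagnostics` to collect
    overlap-guard counters.
    """
    rng = np.random.default_rng(params.seed)
    theta0 = rng.uniform(0.0, math.pi)

    x = np.array([0.0])
    y = np.array([0.0])
    theta = np.array([theta0])
    L = np.array([params.L0])
    ids = np.array([0], dtype=np.int64)
    parent_ids = np.array([-1], dtype=np.int64)
    next_id = 1

    v_gr = params.v_gr
    dt = params.dt
    # steps for one synchronized round: newborn (L0) -> division (2 L0 + 1)
    steps_per_round = int(math.ceil((params.L0 + 1.0) / (v_gr * dt) - 1e-9))

    if diagnostics is None:
        diagnostics = SimulationDiagnostics()

    snapshots: list[ClusterState] = []
    wanted = set(params.snapshot_counts)
    time = 0.0
    division_rounds = 0

    def record():
        parts = [
            Spherocylinder(
                center=np.array([x[i], y[i]]),
                theta=float(theta[i]),
                cyl_length=float(L[i]),
                id=int(ids[i]),
                parent_id=int(parent_ids[i]) if parent_ids[i] >= 0 else None,
            )
            for i in range(len(x))
        ]
        snapshots.append(
            ClusterState(particles=parts, time=time, division_rounds=division_rounds)
        )

    if 1 in wanted:
        record()

    while len(x) < params.N_max:
        n = len(x)
        remaining = steps_per_round
        block = max(1, _NOISE_BLOCK_BYTES // (8 * 3 * n))
        while remaining > 0:
            nsteps = min(block, remaining)
            noise = rng.standard_normal((nsteps, n, 3))
            nc, nd = _kernels.run_chunk(
                x, y, theta, L, noise, dt, params.D0, params.kBT,
                params.epsilon, v_gr, True,
            )
            diagnostics.n_clamped_contacts += int(nc)
            diagnostics.n_deep_overlaps += int(nd)
            diagnostics.n_steps += nsteps * n
            remaining -= nsteps
            time += nsteps * dt

        # synchronized division round
        ex = np.cos(theta)
        ey = np.sin(theta)
        off = 0.5 * (params.L0 + 1.0)
        x = np.concatenate([x + off * ex, x - off * ex])
        y = np.concatenate([y + off * ey, y - off * ey])
        theta = np.concatenate([theta, theta])
        L = np.full(2 * n, params.L0)
        parent_ids = np.concatenate([ids, ids])
        ids = np.arange(next_id, next_id + 2 * n, dtype=np.int64)
        next_id += 2 * n
        division_rounds += 1

        if len(x) in wanted:
            record()

    return snapshots
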