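"""Engine: diffusion coefficients, calibration, forces, integrator, division."""

import math

import numpy as np
import pytest
from scipy import stats

from bdcolony import _kernels
from bdcolony.engine import (
    CUTOFF,
    SimulationDiagnostics,
    SimulationParams,
    bd_step,
    calibrate_growth_velocity,
    diffusion_coefficients,
    gamma_from_velocity,
    grow_and_divide,
    pair_force_torque,
    run_simulation,
    srs_potential,
    total_forces,
)
from bdcolony.geometry import ClusterState, Spherocylinder


def rod(x, y, theta, L, **kw):
    return Spherocylinder(center=np.array([x, y], float), theta=theta, cyl_length=L, **kw)


# --------------------------------------------------------------- parameters


def test_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(Gamma=-1.0)
    with pytest.raises(ValueError):
        SimulationParams(Gamma=0.0)
    with pytest.raises(ValueError):
        SimulationParams(Gamma=1.0, snapshot_counts=(48,))
    with pytest.raises(ValueError):
        SimulationParams(Gamma=1.0, snapshot_counts=(2048,), N_max=1024)
    with pytest.raises(ValueError):
        SimulationParams(Gamma=1.0, L_star_0=0.9)
    p = SimulationParams(Gamma=1.0)
    assert p.snapshot_counts == (32, 64, 128, 256, 512, 1024)
    assert p.L0 == pytest.approx(1.6)
    assert p.dt == pytest.approx(1e-4)


# ------------------------------------------------------ diffusion coefficients


def test_diffusion_coefficients_reference_values():
    """Frozen regression values of the end-corrected rod forms at L* = 2.6."""
    c = diffusion_coefficients(2.6, 0.1)
    assert c.D_par == pytest.approx(0.021264614725721068, rel=1e-12)
    assert c.D_perp == pytest.approx(0.01827050718079408, rel=1e-12)
    assert c.D_theta == pytest.approx(0.010903629432446552, rel=1e-12)


def test_diffusion_coefficient_properties():
    for p in (1.5, 2.6, 5.0, 10.0, 50.0):
        c = diffusion_coefficients(p, 0.1)
        assert c.D_par > c.D_perp > 0
        assert c.D_theta > 0
    # longer rods diffuse slower, and the parallel/perpendicular ratio
    # rises toward its slender-limit value of 2 (logarithmically slowly,
    # since the end corrections decay like 1/ln p)
    long = diffusion_coefficients(200.0, 0.1)
    short = diffusion_coefficients(2.0, 0.1)
    assert long.D_par < short.D_par
    assert short.D_par / short.D_perp < long.D_par / long.D_perp < 2.0
    # linear in D0
    c1 = diffusion_coefficients(2.6, 0.1)
    c2 = diffusion_coefficients(2.6, 0.2)
    assert c2.D_par == pytest.approx(2 * c1.D_par, rel=1e-12)
    with pytest.raises(ValueError):
        diffusion_coefficients(0.5, 0.1)


def test_gamma_round_trip():
    """Gamma -> v_gr -> Gamma recovers the input to 1e-12."""
    for gamma in (0.02, 0.1, 1.0, 16.7, 123.456):
        for lstar in (2.6, 6.0):
            p = SimulationParams(Gamma=gamma, L_star_0=lstar)
            v = calibrate_growth_velocity(p)
            assert v > 0
            assert gamma_from_velocity(p, v) == pytest.approx(gamma, rel=1e-12)


# ----------------------------------------------------------------- potential


def test_srs_potential_closed_forms():
    assert srs_potential(CUTOFF) == 0.0
    assert srs_potential(1.5) == 0.0
    assert srs_potential(1.0) == pytest.approx(1.0)  # 4(1-1)+1 = eps
    assert srs_potential(1.0, epsilon=3.0) == pytest.approx(3.0)
    # continuous at the cutoff and monotonically repulsive below it
    assert srs_potential(CUTOFF - 1e-9) == pytest.approx(0.0, abs=1e-6)
    d = np.linspace(0.21, CUTOFF, 50)
    u = [srs_potential(v) for v in d]
    assert all(a >= b - 1e-12 for a, b in zip(u, u[1:]))
    with pytest.raises(ValueError):
        srs_potential(-0.1)


def test_srs_potential_overlap_guard_warns():
    with pytest.warns(RuntimeWarning):
        u = srs_potential(0.05)
    assert u == pytest.approx(srs_potential(0.2))


# ---------------------------------------------------------- forces / torques


def test_pair_force_newton_third_law():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rod(*rng.uniform(-1, 1, 2), rng.uniform(0, np.pi), rng.uniform(0, 3))
        b = rod(*rng.uniform(-1, 1, 2), rng.uniform(0, np.pi), rng.uniform(0, 3))
        fa, ta, fb, tb = pair_force_torque(a, b)
        assert np.allclose(fa, -fb, atol=1e-12)


def test_pair_force_zero_beyond_cutoff():
    a = rod(0, 0, 0.0, 1.6)
    b = rod(0, 1.2, 0.0, 1.6)  # closest approach 1.2 > 2^(1/6)
    fa, ta, fb, tb = pair_force_torque(a, b)
    assert np.all(fa == 0) and ta == 0 and tb == 0


def test_pair_force_parallel_pair_is_central_and_repulsive():
    a = rod(0, 0, 0.0, 1.6)
    b = rod(0, 1.05, 0.0, 1.6)
    fa, ta, fb, tb = pair_force_torque(a, b)
    assert fa[1] < 0  # pushed apart (a is below b)
    assert fa[0] == pytest.approx(0.0, abs=1e-12)
    assert ta == pytest.approx(0.0, abs=1e-12)
    assert tb == pytest.approx(0.0, abs=1e-12)


def test_pair_force_magnitude_matches_potential_gradient():
    a = rod(0, 0, 0.0, 1.6)
    d0, h = 1.05, 1e-6
    b = rod(0, d0, 0.0, 1.6)
    fa, *_ = pair_force_torque(a, b)
    dU = (srs_potential(d0 + h) - srs_potential(d0 - h)) / (2 * h)
    assert abs(fa[1]) == pytest.approx(abs(dU), rel=1e-5)


def test_off_center_contact_produces_torque():
    # perpendicular T-configuration: b's tip presses on a's side, off-center
    a = rod(0, 0, 0.0, 2.0)
    b = rod(0.7, 1.0, np.pi / 2, 1.0)
    fa, ta, fb, tb = pair_force_torque(a, b)
    assert np.linalg.norm(fa) > 0
    assert ta != 0.0


# ---------------------------------------------------------------- integrator


def test_bd_step_zero_noise_zero_force_is_identity():
    p = SimulationParams(Gamma=1.0)
    state = ClusterState(particles=[rod(0, 0, 0.3, 1.6, id=0)])
    coeffs = [diffusion_coefficients(2.6, p.D0)]
    out = bd_step(state, p, coeffs, np.zeros((1, 2)), np.zeros(1),
                  noise=np.zeros((1, 3)))
    q = out.particles[0]
    assert np.allclose(q.center, 0.0)
    assert q.theta == pytest.approx(0.3)
    assert out.time == pytest.approx(p.dt)


def test_bd_step_deterministic_drift_is_anisotropic():
    """A force along the axis moves the rod D_par/D_perp times farther than
    the same force across it."""
    p = SimulationParams(Gamma=1.0)
    c = diffusion_coefficients(2.6, p.D0)
    coeffs = [c]
    state = ClusterState(particles=[rod(0, 0, 0.0, 1.6, id=0)])
    f_par = np.array([[1.0, 0.0]])
    f_perp = np.array([[0.0, 1.0]])
    out_par = bd_step(state, p, coeffs, f_par, np.zeros(1), noise=np.zeros((1, 3)))
    out_perp = bd_step(state, p, coeffs, f_perp, np.zeros(1), noise=np.zeros((1, 3)))
    dx = out_par.particles[0].center[0]
    dy = out_perp.particles[0].center[1]
    assert dx == pytest.approx(c.D_par * p.dt / p.kBT)
    assert dy == pytest.approx(c.D_perp * p.dt / p.kBT)
    assert dx / dy == pytest.approx(c.D_par / c.D_perp)


def test_kernel_matches_reference_path():
    """The compiled inner loop reproduces the pure-Python reference step for
    an interacting colony over two full division rounds (shared noise)."""
    p = SimulationParams(Gamma=16.7, seed=3, snapshot_counts=(4,), N_max=4)
    rng = np.random.default_rng(12345)
    theta0 = 0.7
    x = np.array([0.0]); y = np.array([0.0])
    th = np.array([theta0]); L = np.array([p.L0])
    steps = math.ceil((p.L0 + 1.0) / (p.v_gr * p.dt) - 1e-9)
    state = ClusterState(particles=[rod(0, 0, theta0, p.L0, id=0)])

    for _ in range(2):
        n = len(x)
        noise = rng.standard_normal((steps, n, 3))
        _kernels.run_chunk(x, y, th, L, noise, p.dt, p.D0, p.kBT,
                           p.epsilon, p.v_gr, True)
        for s in range(steps):
            F, T = total_forces(state, p.epsilon)
            coeffs = [diffusion_coefficients(q.aspect_ratio, p.D0)
                      for q in state.particles]
            state = bd_step(state, p, coeffs, F, T, noise=noise[s])
            state = ClusterState(
                particles=[Spherocylinder(center=q.center, theta=q.theta,
                                          cyl_length=q.cyl_length + p.v_gr * p.dt,
                                          id=q.id)
                           for q in state.particles],
                time=state.time, division_rounds=state.division_rounds)
        rx = np.array([q.center[0] for q in state.particles])
        ry = np.array([q.center[1] for q in state.particles])
        rt = np.array([q.theta for q in state.particles])
        rL = np.array([q.cyl_length for q in state.particles])
        assert np.abs(rx - x).max() < 1e-12
        assert np.abs(ry - y).max() < 1e-12
        assert np.abs(rt - th).max() < 1e-12
        assert np.abs(rL - L).max() < 1e-12
        # synchronized division on both representations
        off = 0.5 * (p.L0 + 1.0)
        ex, ey = np.cos(th), np.sin(th)
        x = np.concatenate([x + off * ex, x - off * ex])
        y = np.concatenate([y + off * ey, y - off * ey])
        th = np.concatenate([th, th])
        L = np.full(2 * n, p.L0)
        state = ClusterState(
            particles=[rod(xx, yy, tt, ll, id=i)
                       for i, (xx, yy, tt, ll) in enumerate(zip(x, y, th, L))],
            division_rounds=state.division_rounds + 1)


def test_free_particle_diffusion_matches_analytic_msd():
    """Non-interacting rods: <|dr|^2> = 2 (D_par + D_perp) t and
    <dtheta^2> = 2 D_theta t, within 3 standard errors over 200 replicates."""
    p = SimulationParams(Gamma=1.0)
    n_rep, n_steps = 200, 2000
    rng = np.random.default_rng(2024)
    x = np.zeros(n_rep)
    y = np.zeros(n_rep)
    th = rng.uniform(0, np.pi, n_rep)
    th0 = th.copy()
    L = np.full(n_rep, p.L0)
    noise = rng.standard_normal((n_steps, n_rep, 3))
    # v_gr = 0: constant length, pure diffusion; interactions off
    _kernels.run_chunk(x, y, th, L, noise, p.dt, p.D0, p.kBT, p.epsilon, 0.0, False)
    t = n_steps * p.dt
    c = diffusion_coefficients(p.L_star_0, p.D0)

    r2 = x**2 + y**2
    expect_r2 = 2.0 * (c.D_par + c.D_perp) * t
    se_r2 = r2.std(ddof=1) / np.sqrt(n_rep)
    assert abs(r2.mean() - expect_r2) < 3 * se_r2

    dth2 = (th - th0) ** 2
    expect_th2 = 2.0 * c.D_theta * t
    se_th2 = dth2.std(ddof=1) / np.sqrt(n_rep)
    assert abs(dth2.mean() - expect_th2) < 3 * se_th2


# ------------------------------------------------------------------ division


def test_grow_and_divide_geometry():
    """At L*_0 = 2.6 a dividing parent yields daughters at r0 +/- 1.3 sigma
    along its axis, each a newborn of cylinder length L0."""
    L0 = 1.6
    theta = 0.4
    parent = rod(2.0, -1.0, theta, 2 * L0 + 1.0 - 1e-13, id=7)
    out = grow_and_divide(ClusterState(particles=[parent]), v_gr=0.0, dt=1.0,
                          L_star_0=2.6)
    assert len(out) == 2
    e = np.array([np.cos(theta), np.sin(theta)])
    d0, d1 = out.particles
    assert np.allclose(d0.center, parent.center + 1.3 * e, atol=1e-10)
    assert np.allclose(d1.center, parent.center - 1.3 * e, atol=1e-10)
    for d in (d0, d1):
        assert d.cyl_length == pytest.approx(L0)
        assert d.theta == theta
        assert d.parent_id == 7
    assert d0.id != d1.id
    assert out.division_rounds == 1
    # daughters' joint tip-to-tip footprint equals the parent's:
    # center separation + one daughter tip-to-tip length = 2 L0 + 2 sigma
    span = abs((d0.center - d1.center) @ e) + L0 + 1.0
    assert span == pytest.approx(2 * L0 + 2.0)


def test_grow_and_divide_below_threshold_only_elongates():
    parent = rod(0, 0, 0.0, 1.6, id=0)
    out = grow_and_divide(ClusterState(particles=[parent]), v_gr=1.0, dt=0.1,
                          L_star_0=2.6)
    assert len(out) == 1
    assert out.particles[0].cyl_length == pytest.approx(1.7)
    assert out.division_rounds == 0


# ------------------------------------------------------------- full pipeline


def test_run_simulation_schedule_and_counts():
    p = SimulationParams(Gamma=16.7, seed=5, snapshot_counts=(2, 8, 32), N_max=32)
    snaps = run_simulation(p)
    assert [len(s) for s in snaps] == [2, 8, 32]
    for s in snaps:
        s.validate()  # counts are 2^k with k = division_rounds
        assert len(s) == 2 ** s.division_rounds
        # every snapshot is taken right after a division: all newborns
        assert np.allclose(s.cyl_lengths(), p.L0)


def test_run_simulation_deterministic_in_seed():
    p = SimulationParams(Gamma=5.0, seed=11, snapshot_counts=(16,), N_max=16)
    a = run_simulation(p)[-1]
    b = run_simulation(p)[-1]
    assert np.array_equal(a.centers(), b.centers())
    assert np.array_equal(a.thetas(), b.thetas())
    c = run_simulation(SimulationParams(Gamma=5.0, seed=12,
                                        snapshot_counts=(16,), N_max=16))[-1]
    assert not np.array_equal(a.centers(), c.centers())


def test_run_simulation_diagnostics_counters():
    diag = SimulationDiagnostics()
    p = SimulationParams(Gamma=16.7, seed=2, snapshot_counts=(32,), N_max=32)
    run_simulation(p, diagnostics=diag)
    assert diag.n_steps > 0
    assert diag.n_clamped_contacts >= 0
    assert diag.n_deep_overlaps >= 0


def test_results_independent_of_d0_vgr_split():
    """Two (D0, v_gr) pairs consistent with the same Gamma give statistically
    indistinguishable order/shape at the 64-particle stage (10 seeds,
    two-sample test at alpha = 0.01)."""
    from bdcolony.morphometrics import eccentricity, nematic_order

    def batch(d0):
        s2, phi = [], []
        for seed in range(1, 11):
            p = SimulationParams(Gamma=1.0, D0=d0, seed=seed,
                                 snapshot_counts=(64,), N_max=64)
            s = run_simulation(p)[-1]
            s2.append(nematic_order(s))
            phi.append(eccentricity(s))
        return np.array(s2), np.array(phi)

    s2_a, phi_a = batch(0.1)
    s2_b, phi_b = batch(0.2)  # double diffusivity => double v_gr, same Gamma
    for a, b in ((s2_a, s2_b), (phi_a, phi_b)):
        p_val = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p_val > 0.01
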