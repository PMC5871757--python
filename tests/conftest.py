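"""Shared fixtures: replicate simulation runs reused across test modules.

The expensive low-Gamma growth runs are computed once per session and shared:
a run that snapshots at both the 32- and 64-particle stages serves the
central-coverage checks (32) and the order-parameter trend checks (64)
simultaneously, since the trajectory up to a given stage does not depend on
how much further the run continues.
"""

from __future__ import annotations

import numpy as np
import pytest

from bdcolony.engine import SimulationParams, run_simulation
from bdcolony.morphometrics import coverage_profile

# replicate seeds for the main acceptance comparisons
SEEDS_10 = tuple(range(1, 11))

GAMMA_GRID = (0.02, 0.1, 1.0, 16.7)


def _run_to_stages(gamma, seed, counts, L_star_0=2.6):
    params = SimulationParams(
        Gamma=gamma,
        L_star_0=L_star_0,
        snapshot_counts=counts,
        N_max=max(counts),
        seed=seed,
    )
    snaps = run_simulation(params)
    return {len(s): s for s in snaps}


@pytest.fixture(scope="session")
def colony_runs():
    """dict[(gamma, seed)] -> {32: state, 64: state} at L*_0 = 2.6.

    Ten seeds per Gamma on the grid {0.02, 0.1, 1, 16.7}.
    """
    out = {}
    for g in GAMMA_GRID:
        for seed in SEEDS_10:
            out[(g, seed)] = _run_to_stages(g, seed, (32, 64))
    return out


@pytest.fixture(scope="session")
def central_coverage(colony_runs):
    """dict[gamma] -> (per-seed central mean g list, per-seed major radius list).

    Coverage of the 32-particle snapshots with dr = 0.5 sigma and 1e4 MC
    points per annulus; central region = annuli with outer edge <= 2 sigma.
    """
    out = {}
    for g in (16.7, 0.02):
        centrals, radii = [], []
        for seed in SEEDS_10:
            state = colony_runs[(g, seed)][32]
            rng = np.random.default_rng(900_000 + seed)
            prof = coverage_profile(state, dr=0.5, n_points=10_000, rng=rng)
            centrals.append(prof.central_mean(2.0))
            nz = np.nonzero(prof.g_values > 0)[0]
            radii.append(float(prof.r_edges[nz[-1] + 1]))
        out[g] = (centrals, radii)
    return out


@pytest.fixture(scope="session")
def long_rod_runs():
    """L*_0 = 6 colonies at the 64-particle stage, Gamma = 10 vs 0.01."""
    out = {}
    for g in (10.0, 0.01):
        out[g] = [
            _run_to_stages(g, seed, (64,), L_star_0=6.0)[64] for seed in range(1, 5)
        ]
    return out


@pytest.fixture(scope="session")
def large_colony_runs():
    """256-particle colonies over the log-spaced Gamma grid, 3 seeds each."""
    out = {}
    for g in GAMMA_GRID:
        out[g] = [_run_to_stages(g, seed, (256,))[256] for seed in range(1, 4)]
    return out
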