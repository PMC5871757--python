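"""Numba-compiled inner loops of the Brownian-dynamics engine.

The driver in :mod:`bdcolony.engine` owns all bookkeeping (division, snapshot
scheduling, random-number generation); these kernels only advance the particle
arrays over a block of time steps.  Gaussian noise is generated outside and
passed in, so a run is a pure function of its seed.

Pair interactions use a Verlet neighbor list built from center distances with
a safety skin; the list is rebuilt whenever accumulated center displacement
plus tip extension from growth could have let an unlisted pair come into
range.  Per-step cost is O(N) for the colony sizes of interest.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# WCA cutoff on the closest-approach distance, in sigma units
CUTOFF = 2.0 ** (1.0 / 6.0)
# minimum separation used inside the force law (overlap guard)
MIN_SEP = 0.2
# separation below which a contact counts as a deep overlap (diagnostic)
DEEP_OVERLAP = 0.5
SKIN = 1.0

_PARALLEL_EPS = 1e-12


@njit(cache=True, fastmath=False)
def seg_seg_closest(cax, cay, eax, eay, ha, cbx, cby, ebx, eby, hb):
    """Closest points between two centered segments.

    Returns (d, pax, pay, pbx, pby).  Mirrors the exact clamped minimization
    of geometry.closest_approach, including the parallel-overlap midpoint
    tie-break.
    """
    rx = cax - cbx
    ry = cay - cby
    b = eax * ebx + eay * eby
    f = ebx * rx + eby * ry
    c = eax * rx + eay * ry
    denom = 1.0 - b * b

    if ha == 0.0 and hb == 0.0:
        s = 0.0
        t = 0.0
    elif ha == 0.0:
        s = 0.0
        t = min(max(f, -hb), hb)
    elif hb == 0.0:
        s = min(max(-c, -ha), ha)
        t = 0.0
    elif denom > _PARALLEL_EPS:
        s = (b * f - c) / denom
        s = min(max(s, -ha), ha)
        t = b * s + f
        if t < -hb or t > hb:
            t = min(max(t, -hb), hb)
            s = min(max(b * t - c, -ha), ha)
    else:
        # parallel: midpoint of the overlap interval on segment a
        proj = -c
        lo = max(-ha, proj - hb)
        hi = min(ha, proj + hb)
        if lo <= hi:
            s = 0.5 * (lo + hi)
        elif proj < 0.0:
            s = -ha
        else:
            s = ha
        t = min(max(b * s + f, -hb), hb)

    pax = cax + s * eax
    pay = cay + s * eay
    pbx = cbx + t * ebx
    pby = cby + t * eby
    dx = pax - pbx
    dy = pay - pby
    d = np.sqrt(dx * dx + dy * dy)
    return d, pax, pay, pbx, pby


@njit(cache=True)
def build_pairs(x, y, half_len, pairs):
    """All-pairs scan filling the Verlet list; returns the pair count.

    A pair enters the list when its centers are within interaction range
    (sum of half-lengths + WCA cutoff) plus the skin.
    """
    n = x.shape[0]
    np_ = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            rc = half_len[i] + half_len[j] + CUTOFF + SKIN
            if dx * dx + dy * dy < rc * rc:
                pairs[np_, 0] = i
                pairs[np_, 1] = j
                np_ += 1
    return np_


@njit(cache=True)
def compute_forces(x, y, cth, sth, half_len, pairs, n_pairs, eps, fx, fy, tq):
    """SRS (WCA on closest approach) forces and torques for listed pairs.

    Returns (n_clamped, n_deep): counts of contacts below the overlap guard
    and below the deep-overlap diagnostic threshold.
    """
    n = x.shape[0]
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0
    n_clamped = 0
    n_deep = 0
    for k in range(n_pairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        rc = half_len[i] + half_len[j] + CUTOFF
        if dx * dx + dy * dy >= rc * rc:
            continue
        d, pax, pay, pbx, pby = seg_seg_closest(
            x[i], y[i], cth[i], sth[i], half_len[i],
            x[j], y[j], cth[j], sth[j], half_len[j],
        )
        if d >= CUTOFF:
            continue
        if d < DEEP_OVERLAP:
            n_deep += 1
        nx = pax - pbx
        ny = pay - pby
        if d < MIN_SEP:
            n_clamped += 1
            if d > 1e-12:
                nx /= d
                ny /= d
            else:
                # coincident axes: push along the center line (or x if that
                # is degenerate too)
                cd = np.sqrt(dx * dx + dy * dy)
                if cd > 1e-12:
                    nx = dx / cd
                    ny = dy / cd
                else:
                    nx = 1.0
                    ny = 0.0
            d_eff = MIN_SEP
        else:
            nx /= d
            ny /= d
            d_eff = d
        inv = 1.0 / d_eff
        inv6 = inv ** 6
        # -dU/dd with U = 4 eps (d^-12 - d^-6) + eps
        fmag = 24.0 * eps * inv * inv6 * (2.0 * inv6 - 1.0)
        fxi = fmag * nx
        fyi = fmag * ny
        fx[i] += fxi
        fy[i] += fyi
        fx[j] -= fxi
        fy[j] -= fyi
        tq[i] += (pax - x[i]) * fyi - (pay - y[i]) * fxi
        tq[j] += (pbx - x[j]) * (-fyi) - (pby - y[j]) * (-fxi)
    return n_clamped, n_deep


@njit(cache=True)
def rod_diffusion(p, D0):
    """Tirado-Garcia de la Torre end-corrected rod coefficients.

    p is the aspect ratio (total length / diameter); returns
    (D_par, D_perp, D_theta) with D0 the diffusional scale (sigma = 1).
    """
    lnp = np.log(p)
    nu_par = -0.207 + 0.980 / p - 0.133 / (p * p)
    nu_perp = 0.839 + 0.185 / p + 0.233 / (p * p)
    nu_rot = -0.662 + 0.917 / p - 0.050 / (p * p)
    d_par = D0 * (lnp + nu_par) / (2.0 * p)
    d_perp = D0 * (lnp + nu_perp) / (4.0 * p)
    d_rot = 3.0 * D0 * (lnp + nu_rot) / (p * p * p)
    return d_par, d_perp, d_rot


@njit(cache=True)
def run_chunk(x, y, theta, L, noise, dt, D0, kBT, eps, v_gr, interacting):
    """Advance the colony by noise.shape[0] BD steps (force, move, grow).

    noise has shape (n_steps, N, 3): parallel, perpendicular and angular
    standard gaussians per particle per step.  Arrays are updated in place.
    Growth is synchronized (every cell has the same length at every step),
    so the aspect-ratio-dependent diffusion coefficients are evaluated once
    per step, not once per particle.  Returns (n_clamped, n_deep)
    accumulated over the chunk.
    """
    n_steps = noise.shape[0]
    n = x.shape[0]
    cth = np.cos(theta)
    sth = np.sin(theta)
    half_len = 0.5 * L
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    pairs = np.empty((n * (n - 1) // 2 if n > 1 else 1, 2), dtype=np.int64)
    n_pairs = 0
    # reference state for neighbor-list validity
    x0 = x.copy()
    y0 = y.copy()
    grow0 = 0.0
    max_disp2 = 1.0e30  # force a build on entry
    n_clamped = 0
    n_deep = 0
    margin = 0.5 * SKIN

    for step in range(n_steps):
        if interacting and n > 1:
            if np.sqrt(max_disp2) + grow0 > margin:
                for i in range(n):
                    half_len[i] = 0.5 * L[i]
                n_pairs = build_pairs(x, y, half_len, pairs)
                for i in range(n):
                    x0[i] = x[i]
                    y0[i] = y[i]
                grow0 = 0.0
                max_disp2 = 0.0
            for i in range(n):
                half_len[i] = 0.5 * L[i]
            nc, nd = compute_forces(
                x, y, cth, sth, half_len, pairs, n_pairs, eps, fx, fy, tq
            )
            n_clamped += nc
            n_deep += nd

        # coefficients at the current (shared) aspect ratio, before the move
        d_par, d_perp, d_rot = rod_diffusion(L[0] + 1.0, D0)
        mob_par = d_par * dt / kBT
        mob_perp = d_perp * dt / kBT
        mob_rot = d_rot * dt / kBT
        sd_par = np.sqrt(2.0 * d_par * dt)
        sd_perp = np.sqrt(2.0 * d_perp * dt)
        sd_rot = np.sqrt(2.0 * d_rot * dt)
        for i in range(n):
            ci = cth[i]
            si = sth[i]
            # parallel / perpendicular force components (u = (-s, c))
            fpar = fx[i] * ci + fy[i] * si
            fperp = -fx[i] * si + fy[i] * ci
            dpar = mob_par * fpar + sd_par * noise[step, i, 0]
            dperp = mob_perp * fperp + sd_perp * noise[step, i, 1]
            x[i] += dpar * ci - dperp * si
            y[i] += dpar * si + dperp * ci
            theta[i] += mob_rot * tq[i] + sd_rot * noise[step, i, 2]
            cth[i] = np.cos(theta[i])
            sth[i] = np.sin(theta[i])
            L[i] += v_gr * dt
            dx = x[i] - x0[i]
            dy = y[i] - y0[i]
            disp2 = dx * dx + dy * dy
            if disp2 > max_disp2:
                max_disp2 = disp2
        grow0 += 0.5 * v_gr * dt

    return n_clamped, n_deep
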