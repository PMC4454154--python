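"""Numba-compiled hot paths for the Monte Carlo sweeps.

Cell codes follow :class:`evapkmc.lattice.CellKind`:
0 = substrate, 1 = liquid, 2 = vapor, 3 = particle.

All kernels take the raw int8 grid plus precomputed coefficient lookup
tables (`coefL[kind]` = bond coefficient between liquid and that kind,
`coefD[kind]` = particle-vs-liquid coefficient difference), so the per-cell
stencil evaluation is a pure table lookup.  Randomness comes from a
``numpy.random.Generator`` passed in from the caller; numba advances the
same bit-generator state, so interleaving python-level and kernel-level
draws stays reproducible from one seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Stencil: 6 nearest offsets then 12 face-diagonal next-nearest offsets,
# the latter weighted by 1/sqrt(2).  Read by the kernels as compile-time
# constants.
_OFF = np.array(
    [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)
_W = np.concatenate([np.ones(6), np.full(12, 1.0 / math.sqrt(2.0))])


@njit(cache=True)
def delta_flip_kernel(grid, x, y, k, D, H, coefL, mu, c):
    """dE of toggling liquid<->vapor at (x, y, k) from the local stencil."""
    s = 0.0
    for i in range(18):
        kk = k + _OFF[i, 2]
        if kk < 0 or kk > H:
            continue
        nb = grid[(x + _OFF[i, 0]) % D, (y + _OFF[i, 1]) % D, kk]
        s += _W[i] * coefL[nb]
    if grid[x, y, k] == 1:  # liquid -> vapor: bonds and -mu*l are lost
        return c * s + mu
    return -(c * s + mu)


@njit(cache=True)
def delta_swap_kernel(grid, ax, ay, ak, bx, by, bk, D, H, coefD, c):
    """dE of exchanging the particle at a with the liquid at b (adjacent)."""
    sa = 0.0
    for i in range(18):
        kk = ak + _OFF[i, 2]
        if kk < 0 or kk > H:
            continue
        xx = (ax + _OFF[i, 0]) % D
        yy = (ay + _OFF[i, 1]) % D
        if xx == bx and yy == by and kk == bk:
            continue
        sa += _W[i] * coefD[grid[xx, yy, kk]]
    sb = 0.0
    for i in range(18):
        kk = bk + _OFF[i, 2]
        if kk < 0 or kk > H:
            continue
        xx = (bx + _OFF[i, 0]) % D
        yy = (by + _OFF[i, 1]) % D
        if xx == ax and yy == ay and kk == ak:
            continue
        sb += _W[i] * coefD[grid[xx, yy, kk]]
    return c * (sa - sb)


@njit(cache=True)
def sweep_fluid_kernel(grid, D, H, coefL, mu, c, kT, rng):
    """One evaporation/condensation sweep: visit every fluid cell once.

    Visiting order is freshly shuffled each call; accepted toggles take
    effect immediately (sequential updating).  Returns the accepted count.
    """
    order = np.empty(D * D * H, dtype=np.int64)
    m = 0
    for x in range(D):
        for y in range(D):
            for k in range(1, H + 1):
                if grid[x, y, k] != 3:
                    order[m] = (x * D + y) * H + (k - 1)
                    m += 1
    active = order[:m]
    rng.shuffle(active)
    accepted = 0
    for i in range(m):
        idx = active[i]
        k = idx % H + 1
        y = (idx // H) % D
        x = idx // (H * D)
        de = delta_flip_kernel(grid, x, y, k, D, H, coefL, mu, c)
        if rng.random() < math.exp(-de / kT):
            grid[x, y, k] = 3 - grid[x, y, k]  # 1 <-> 2
            accepted += 1
    return accepted


@njit(cache=True)
def sweep_particles_kernel(grid, particles, D, H, coefD, n_mov, c, kT, rng):
    """One particle random-walk phase: n_mov attempts per particle.

    Each attempt draws one of the 6 nearest directions uniformly (the draw
    happens before checking the target, so immobilized particles consume the
    same stream); moves are only into liquid cells.  ``particles`` is the
    (P, 3) coordinate table and is updated in place.  Returns the accepted
    count.
    """
    accepted = 0
    for p in range(len(particles)):
        for _ in range(n_mov):
            d = rng.integers(0, 6)
            ax, ay, ak = particles[p, 0], particles[p, 1], particles[p, 2]
            tx = (ax + _OFF[d, 0]) % D
            ty = (ay + _OFF[d, 1]) % D
            tk = ak + _OFF[d, 2]
            if tk < 0 or tk > H:
                continue
            if grid[tx, ty, tk] != 1:
                continue
            de = delta_swap_kernel(grid, ax, ay, ak, tx, ty, tk, D, H, coefD, c)
            if rng.random() < math.exp(-de / kT):
                grid[ax, ay, ak] = 1
                grid[tx, ty, tk] = 3
                particles[p, 0] = tx
                particles[p, 1] = ty
                particles[p, 2] = tk
                accepted += 1
    return accepted
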