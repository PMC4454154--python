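"""Lattice-gas Hamiltonian and incremental energy changes.

The total energy is

    E = -c * sum_<ij> w_ij * eps(kind_i, kind_j)  -  mu * sum_i l_i

where the pair sum runs once over every unordered nearest (w=1) and
next-nearest (w=1/sqrt(2)) pair, ``eps`` couples liquid-liquid, liquid-
particle, particle-particle, liquid-substrate and particle-substrate pairs
(vapor couples to nothing; substrate-substrate pairs are excluded), ``l_i``
is the liquid indicator, and ``c = 1/(1+sqrt(2))`` rescales the widened
stencil so the effective coordination ``c*(6 + 12/sqrt(2)) = 6`` matches a
nearest-neighbor-only model.  That keeps the bulk liquid/vapor coexistence
point at ``mu = -3`` for ``eps_ll = 1``; the film is evaporated by holding
``mu`` below it.

``total_energy`` is the slow reference implementation used as an oracle;
the Monte Carlo hot path lives in :mod:`evapkmc._kernels` and is checked
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lattice import (
    ALL_OFFSETS,
    OFFSET_WEIGHTS,
    CellKind,
    LatticeState,
)

__all__ = [
    "INTERACTION_SCALE",
    "InteractionParams",
    "total_energy",
    "delta_flip",
    "delta_swap",
]

#: Coordination-consistency factor c = 1/(1+sqrt(2)): with it the summed
#: stencil weight 6 + 12/sqrt(2) is rescaled back to 6.
INTERACTION_SCALE = 1.0 / (1.0 + math.sqrt(2.0))


@dataclass(frozen=True)
class InteractionParams:
    """Pair couplings and thermal energy, all in units of ``eps_ll``.

    ``eps_ll = 1`` fixes the energy unit.  The couplings to the substrate
    default to the bulk-liquid convention ``eps_ls = eps_ll`` and
    ``eps_ns = eps_ln``; both may be overridden explicitly.
    """

    eps_ll: float = 1.0
    eps_ln: float = 1.5
    eps_nn: float = 2.0
    eps_ls: Optional[float] = None
    eps_ns: Optional[float] = None
    kT: float = 0.2
    interaction_scale: float = INTERACTION_SCALE

    def __post_init__(self):
        if self.eps_ls is None:
            object.__setattr__(self, "eps_ls", self.eps_ll)
        if self.eps_ns is None:
            object.__setattr__(self, "eps_ns", self.eps_ln)
        if self.kT <= 0:
            raise ValueError(f"kT must be > 0, got {self.kT}")

    def pair_matrix(self) -> np.ndarray:
        """4x4 coupling matrix indexed by (CellKind, CellKind).

        Vapor rows/columns are zero and the substrate-substrate entry is
        zero (those pairs never change and are excluded by convention).
        """
        m = np.zeros((4, 4))
        L, N, S = CellKind.LIQUID, CellKind.PARTICLE, CellKind.SUBSTRATE
        m[L, L] = self.eps_ll
        m[L, N] = m[N, L] = self.eps_ln
        m[N, N] = self.eps_nn
        m[L, S] = m[S, L] = self.eps_ls
        m[N, S] = m[S, N] = self.eps_ns
        return m

    def liquid_coeffs(self) -> np.ndarray:
        """Bond coefficient between a liquid cell and a neighbor of each kind."""
        return np.array([self.eps_ls, self.eps_ll, 0.0, self.eps_ln])

    def particle_coeffs(self) -> np.ndarray:
        """Bond coefficient between a particle cell and a neighbor of each kind."""
        return np.array([self.eps_ns, self.eps_ln, 0.0, self.eps_nn])


# Unordered-pair enumeration: keep one representative of each +-offset pair.
_HALF = [i for i, (dx, dy, dk) in enumerate(ALL_OFFSETS)
         if (dx, dy, dk) > (-dx, -dy, -dk)]


def total_energy(state: LatticeState, params: InteractionParams, mu: float) -> float:
    """Full Hamiltonian evaluated by direct pair enumeration (reference oracle).

    O(D^2 * H * 9) python loop; intended for small lattices and testing, not
    for the simulation hot path.
    """
    grid = state.grid
    D, H = state.D, state.H
    m = params.pair_matrix()
    pair_sum = 0.0
    for idx in _HALF:
        dx, dy, dk = ALL_OFFSETS[idx]
        w = OFFSET_WEIGHTS[idx]
        for x in range(D):
            for y in range(D):
                for k in range(H + 1):
                    kk = k + dk
                    if kk < 0 or kk > H:
                        continue
                    a = grid[x, y, k]
                    b = grid[(x + dx) % D, (y + dy) % D, kk]
                    pair_sum += w * m[a, b]
    n_liquid = np.count_nonzero(grid == CellKind.LIQUID)
    return -params.interaction_scale * pair_sum - mu * float(n_liquid)


def delta_flip(
    state: LatticeState,
    cell,
    params: InteractionParams,
    mu: float,
) -> float:
    """Energy change of toggling LIQUID <-> VAPOR at ``cell``.

    Computed locally from the 18-neighbor stencil; agrees with the
    ``total_energy`` difference to machine precision.
    """
    from ._kernels import delta_flip_kernel

    x, y, k = (int(v) for v in cell)
    kind = state.grid[x, y, k]
    if kind not in (CellKind.LIQUID, CellKind.VAPOR):
        raise ValueError(
            f"delta_flip requires a LIQUID or VAPOR cell, got {CellKind(kind).name}"
        )
    return float(
        delta_flip_kernel(
            state.grid, x, y, k, state.D, state.H,
            params.liquid_coeffs(), mu, params.interaction_scale,
        )
    )


def delta_swap(
    state: LatticeState,
    particle_cell,
    liquid_cell,
    params: InteractionParams,
) -> float:
    """Energy change of exchanging a particle with a nearest-neighbor liquid.

    The chemical-potential term cancels (the liquid count is unchanged), so
    the result is independent of ``mu``.
    """
    from ._kernels import delta_swap_kernel

    ax, ay, ak = (int(v) for v in particle_cell)
    bx, by, bk = (int(v) for v in liquid_cell)
    D, H = state.D, state.H
    if state.grid[ax, ay, ak] != CellKind.PARTICLE:
        raise ValueError("particle_cell must hold a PARTICLE")
    if state.grid[bx, by, bk] != CellKind.LIQUID:
        raise ValueError("liquid_cell must hold LIQUID")
    dxy = ((ax - bx) % D, (ay - by) % D)
    sep = sorted((min(dxy[0], D - dxy[0]), min(dxy[1], D - dxy[1]), abs(ak - bk)))
    if sep != [0, 0, 1]:
        raise ValueError("cells must be nearest neighbors")
    coeff_diff = params.particle_coeffs() - params.liquid_coeffs()
    return float(
        delta_swap_kernel(
            state.grid, ax, ay, ak, bx, by, bk, D, H,
            coeff_diff, params.interaction_scale,
        )
    )
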