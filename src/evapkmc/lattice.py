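"""Simulation domain: 3D cell grid, neighbor topology, initial states.

The domain is a square-based prism of ``D x D x (H+1)`` cubic cells.  Layer 0
is a rigid substrate; layers ``1..H`` start out filled with liquid and
particles and evolve during the simulation.  Lateral boundaries are periodic
(toroidal); the vertical direction is open — cells above the top layer behave
as permanent vapor and contribute no interaction energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Union

import numpy as np

__all__ = [
    "CellKind",
    "EXTERIOR",
    "LatticeState",
    "NeighborTopology",
    "default_topology",
    "build_initial_state",
    "neighbors",
    "dried_fraction",
    "liquid_fraction",
    "save_snapshot",
    "load_snapshot",
]


class CellKind(IntEnum):
    """Occupancy of a single lattice cell.

    Exactly one kind per cell; the indicator triplet ``(l, n, s)`` used by the
    Hamiltonian is mutually exclusive: ``l=1`` iff LIQUID, ``n=1`` iff
    PARTICLE, ``s=1`` iff SUBSTRATE, all zero for VAPOR.
    """

    SUBSTRATE = 0
    LIQUID = 1
    VAPOR = 2
    PARTICLE = 3


#: Sentinel returned by :func:`neighbors` for offsets that leave the grid
#: vertically.  Exterior cells interact like vapor: zero coupling.
EXTERIOR = None

# 6 nearest offsets: unit steps along each axis.
_NEAREST = np.array(
    [
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
    ],
    dtype=np.int64,
)

# 12 next-nearest offsets: face diagonals at distance sqrt(2).
_NEXT_NEAREST = np.array(
    [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)

NEXT_NEAREST_WEIGHT = 1.0 / math.sqrt(2.0)

#: All 18 offsets stacked (first 6 nearest, then 12 next-nearest).
ALL_OFFSETS = np.vstack([_NEAREST, _NEXT_NEAREST])

#: Interaction weight per offset: 1 for nearest, 1/sqrt(2) for next-nearest.
OFFSET_WEIGHTS = np.concatenate(
    [np.ones(6), np.full(12, NEXT_NEAREST_WEIGHT)]
)


@dataclass(frozen=True)
class NeighborTopology:
    """The 6 + 12 neighbor stencil of the cubic lattice."""

    nearest_offsets: np.ndarray = field(default_factory=lambda: _NEAREST.copy())
    next_nearest_offsets: np.ndarray = field(
        default_factory=lambda: _NEXT_NEAREST.copy()
    )
    next_nearest_weight: float = NEXT_NEAREST_WEIGHT


def default_topology() -> NeighborTopology:
    return NeighborTopology()


@dataclass
class LatticeState:
    """The evolving simulation state.

    Attributes
    ----------
    grid
        ``(D, D, H+1)`` int8 array of :class:`CellKind` codes; the last axis
        is the vertical one and index 0 is the substrate layer.
    z
        Side-wall aspect ratio used to build the film (``H = round(z * D)``).
    step_index
        Number of completed Monte Carlo steps.
    seed
        Seed used to build the initial configuration (metadata only).
    """

    grid: np.ndarray
    z: float
    step_index: int = 0
    seed: Optional[int] = None

    @property
    def D(self) -> int:
        return self.grid.shape[0]

    @property
    def H(self) -> int:
        return self.grid.shape[2] - 1

    @property
    def particle_count(self) -> int:
        return int(np.count_nonzero(self.grid == CellKind.PARTICLE))

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.z, self.step_index, self.seed)

    def validate(self) -> None:
        """Raise if the structural invariants do not hold."""
        if self.grid.ndim != 3 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be a (D, D, H+1) array")
        if not np.all(self.grid[:, :, 0] == CellKind.SUBSTRATE):
            raise ValueError("layer 0 must be entirely substrate")
        if np.any(self.grid[:, :, 1:] == CellKind.SUBSTRATE):
            raise ValueError("substrate may only appear in layer 0")


def build_initial_state(
    D: int,
    z: float,
    phi: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> LatticeState:
    """Build the pre-drying film: liquid plus randomly placed particles.

    ``H = round(z * D)`` fluid layers sit on one substrate layer.  Exactly
    ``round(phi * D**2 * H)`` particle cells are drawn uniformly without
    replacement from the fluid cells; every other fluid cell is liquid.  There
    is no vapor initially.

    Parameters
    ----------
    D
        Lateral side length in cells (>= 4).
    z
        Aspect ratio; the film height is ``round(z * D)`` and must be >= 2.
    phi
        Particle volume fraction in [0, 1).
    seed, rng
        Either a seed (a fresh generator is created) or an explicit
        generator whose stream is consumed.  ``rng`` wins if both are given.
    """
    if D < 4:
        raise ValueError(f"D must be >= 4, got {D}")
    if not (0.0 <= phi < 1.0):
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    H = round(z * D)
    if H < 2:
        raise ValueError(
            f"film too thin to simulate: round(z*D) = {H} < 2 (z={z}, D={D})"
        )
    n_fluid = D * D * H
    n_particles = round(phi * n_fluid)
    if phi > 0 and n_particles == 0:
        warnings.warn(
            f"phi={phi} yields zero particles on a {D}x{D}x{H} film",
            stacklevel=2,
        )
    grid = np.full((D, D, H + 1), CellKind.LIQUID, dtype=np.int8)
    grid[:, :, 0] = CellKind.SUBSTRATE
    if n_particles:
        if rng is None:
            rng = np.random.default_rng(seed)
        flat = rng.choice(n_fluid, size=n_particles, replace=False)
        x, y, k = np.unravel_index(flat, (D, D, H))
        grid[x, y, k + 1] = CellKind.PARTICLE
    return LatticeState(grid=grid, z=float(z), seed=seed)


def neighbors(
    cell: Union[tuple, np.ndarray],
    D: int,
    H: int,
    topology: Optional[NeighborTopology] = None,
) -> list:
    """Enumerate the 18 stencil entries of ``cell`` as ``(index, weight)``.

    Lateral coordinates wrap modulo ``D``; vertical overflow (below the
    substrate or above layer ``H``) is reported as ``(EXTERIOR, weight)``.
    """
    x, y, k = (int(v) for v in cell)
    if not (0 <= x < D and 0 <= y < D and 0 <= k <= H):
        raise ValueError(f"cell {cell!r} outside a {D}x{D}x{H + 1} grid")
    if topology is None:
        offsets, weights = ALL_OFFSETS, OFFSET_WEIGHTS
    else:
        offsets = np.vstack(
            [topology.nearest_offsets, topology.next_nearest_offsets]
        )
        weights = np.concatenate(
            [
                np.ones(len(topology.nearest_offsets)),
                np.full(
                    len(topology.next_nearest_offsets),
                    topology.next_nearest_weight,
                ),
            ]
        )
    out = []
    for (dx, dy, dk), w in zip(offsets, weights):
        kk = k + dk
        if kk < 0 or kk > H:
            out.append((EXTERIOR, float(w)))
        else:
            out.append(((int((x + dx) % D), int((y + dy) % D), int(kk)), float(w)))
    return out


def dried_fraction(state: LatticeState) -> float:
    """Fraction of substrate sites with no solvent directly on top.

    A lateral site is dried when its layer-1 cell is vapor or particle; this
    is the coverage variable that drives the sigmoidal chemical-potential
    schedule.
    """
    layer1 = state.grid[:, :, 1]
    return float(np.count_nonzero(layer1 != CellKind.LIQUID)) / layer1.size


def liquid_fraction(state: LatticeState) -> float:
    """Liquid cells as a fraction of the ``D*D*H`` fluid volume."""
    fluid = state.grid[:, :, 1:]
    return float(np.count_nonzero(fluid == CellKind.LIQUID)) / fluid.size


def save_snapshot(state: LatticeState, path, **attrs) -> None:
    """Write the state to HDF5 (dataset ``grid`` of byte codes + metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        ds = f.create_dataset(
            "grid", data=state.grid, compression="gzip", track_times=False
        )
        ds.attrs["D"] = state.D
        ds.attrs["H"] = state.H
        ds.attrs["z"] = state.z
        ds.attrs["step_index"] = state.step_index
        if state.seed is not None:
            ds.attrs["seed"] = state.seed
        for key, val in attrs.items():
            ds.attrs[key] = val


def load_snapshot(path) -> LatticeState:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["grid"]
        grid = np.asarray(ds, dtype=np.int8)
        z = float(ds.attrs.get("z", (grid.shape[2] - 1) / grid.shape[0]))
        step_index = int(ds.attrs.get("step_index", 0))
        seed = ds.attrs.get("seed")
        seed = int(seed) if seed is not None else None
    state = LatticeState(grid=grid, z=z, step_index=step_index, seed=seed)
    state.validate()
    return state
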