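"""Metropolis Monte Carlo dynamics of the evaporating film.

One MC step consists of two phases:

1. every liquid and vapor cell, in a freshly shuffled order, attempts a
   liquid<->vapor toggle (evaporation/condensation);
2. every particle makes ``n_mov`` random-walk attempts into nearest-neighbor
   liquid cells.

Moves are accepted with the Metropolis probability min(1, exp(-dE/kT)).
The chemical potential is refreshed once per step from the current dried
fraction via the schedule, so the trace maps mu(nu) directly.  The run
terminates when no liquid remains or ``max_steps`` is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .energetics import InteractionParams
from .lattice import CellKind, LatticeState, dried_fraction, liquid_fraction
from .schedule import MuSchedule

__all__ = [
    "DynamicsConfig",
    "RunTrace",
    "metropolis_accept",
    "sweep_phase_fluid",
    "sweep_phase_particles",
    "run",
]


@dataclass(frozen=True)
class DynamicsConfig:
    schedule: MuSchedule
    n_mov: int = 20
    max_steps: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.n_mov < 0:
            raise ValueError(f"n_mov must be >= 0, got {self.n_mov}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass
class RunTrace:
    """Per-step time series of the run observables."""

    step: list = field(default_factory=list)
    mu: list = field(default_factory=list)
    nu: list = field(default_factory=list)
    liquid_fraction: list = field(default_factory=list)
    accepted_flips: list = field(default_factory=list)
    accepted_swaps: list = field(default_factory=list)

    def append(self, step, mu, nu, liq, flips, swaps) -> None:
        self.step.append(step)
        self.mu.append(mu)
        self.nu.append(nu)
        self.liquid_fraction.append(liq)
        self.accepted_flips.append(flips)
        self.accepted_swaps.append(swaps)

    def __len__(self) -> int:
        return len(self.step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "mu": self.mu,
                "nu": self.nu,
                "liquid_fraction": self.liquid_fraction,
                "accepted_flips": self.accepted_flips,
                "accepted_swaps": self.accepted_swaps,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def metropolis_accept(delta_e: float, kT: float, uniform_draw: float) -> bool:
    """Accept iff ``uniform_draw < min(1, exp(-delta_e / kT))``."""
    if kT <= 0:
        raise ValueError(f"kT must be > 0, got {kT}")
    if delta_e <= 0:
        return True
    return uniform_draw < math.exp(-delta_e / kT)


def sweep_phase_fluid(
    state: LatticeState,
    params: InteractionParams,
    mu: float,
    rng: np.random.Generator,
) -> int:
    """Run one evaporation/condensation sweep in place; return accepted count."""
    return int(
        _kernels.sweep_fluid_kernel(
            state.grid,
            state.D,
            state.H,
            params.liquid_coeffs(),
            float(mu),
            params.interaction_scale,
            params.kT,
            rng,
        )
    )


def _particle_table(state: LatticeState) -> np.ndarray:
    """(P, 3) coordinates of all particles, in C scan order."""
    return np.argwhere(state.grid == CellKind.PARTICLE).astype(np.int64)


def sweep_phase_particles(
    state: LatticeState,
    params: InteractionParams,
    n_mov: int,
    rng: np.random.Generator,
    particles: Optional[np.ndarray] = None,
) -> int:
    """Run one particle random-walk phase in place; return accepted count.

    ``particles`` may carry the coordinate table between steps to avoid
    rescanning the grid; it is updated in place.
    """
    if particles is None:
        particles = _particle_table(state)
    if len(particles) == 0 or n_mov == 0:
        return 0
    coeff_diff = params.particle_coeffs() - params.liquid_coeffs()
    return int(
        _kernels.sweep_particles_kernel(
            state.grid,
            particles,
            state.D,
            state.H,
            coeff_diff,
            int(n_mov),
            params.interaction_scale,
            params.kT,
            rng,
        )
    )


def run(
    state: LatticeState,
    params: InteractionParams,
    config: DynamicsConfig,
    rng: Optional[np.random.Generator] = None,
    step_callback: Optional[Callable[[LatticeState, "RunTrace"], None]] = None,
) -> tuple[LatticeState, RunTrace]:
    """Evolve ``state`` in place until dry or ``max_steps``; return it + trace.

    The particle count and the substrate layer are invariant over the run.
    ``rng`` defaults to a fresh generator seeded with ``config.seed``; pass
    one explicitly to share a stream with the initial-state construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    particles = _particle_table(state)
    trace = RunTrace()
    for _ in range(config.max_steps):
        nu = dried_fraction(state)
        mu = config.schedule(nu)
        flips = sweep_phase_fluid(state, params, mu, rng)
        swaps = sweep_phase_particles(state, params, config.n_mov, rng, particles)
        state.step_index += 1
        liq = liquid_fraction(state)
        trace.append(state.step_index, mu, nu, liq, flips, swaps)
        if step_callback is not None:
            step_callback(state, trace)
        if liq == 0.0:
            break
    return state, trace
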