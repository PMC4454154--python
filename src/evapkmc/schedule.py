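"""Chemical-potential schedules.

The effective chemical potential mu folds the disjoining-pressure
contribution of a thinning film into a single evaporation bias.  Two
policies are provided: a constant mu, and a sigmoidal jump driven by the
dried-substrate fraction nu,

    mu(nu) = mu0 - delta / (1 + exp(-(nu - nu_c) / sigma))

i.e. mu stays near ``mu0`` while the substrate is mostly wet and drops by
``delta`` (total jump magnitude) once the dried coverage passes the
critical value ``nu_c``; ``sigma`` sets the sharpness of the transition.
The drop makes mu more negative, triggering rapid dry-out of the remaining
solvent and with it the secondary, finer structure of dual-scale patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.special import expit

__all__ = ["MuSchedule", "mu_of_nu"]

#: Bulk liquid/vapor coexistence point for eps_ll = 1; schedules should
#: start below it for the film to evaporate.
COEXISTENCE_MU = -3.0


@dataclass(frozen=True)
class MuSchedule:
    """Constant or sigmoidal chemical-potential policy.

    Use :meth:`constant` / :meth:`sigmoidal` to construct; ``schedule(nu)``
    evaluates it.
    """

    kind: str  # "constant" | "sigmoidal"
    mu0: float
    delta: float = 0.0
    sigma: float = 0.01
    nu_c: float = 0.15

    def __post_init__(self):
        if self.kind not in ("constant", "sigmoidal"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "sigmoidal":
            if self.sigma <= 0:
                raise ValueError(f"sigma must be > 0, got {self.sigma}")
            if self.delta < 0:
                raise ValueError(f"delta must be >= 0, got {self.delta}")
            if not (0.0 < self.nu_c < 1.0):
                raise ValueError(f"nu_c must be in (0, 1), got {self.nu_c}")
        if self.mu0 >= COEXISTENCE_MU:
            warnings.warn(
                f"mu0={self.mu0} is not below the coexistence point "
                f"{COEXISTENCE_MU}; the film will not be in the vapor regime",
                stacklevel=3,
            )

    @classmethod
    def constant(cls, mu0: float) -> "MuSchedule":
        return cls(kind="constant", mu0=mu0)

    @classmethod
    def sigmoidal(
        cls,
        mu0: float,
        delta: float,
        sigma: float = 0.01,
        nu_c: float = 0.15,
    ) -> "MuSchedule":
        return cls(kind="sigmoidal", mu0=mu0, delta=delta, sigma=sigma, nu_c=nu_c)

    def __call__(self, nu: float) -> float:
        return mu_of_nu(self, nu)


def mu_of_nu(schedule: MuSchedule, nu: float) -> float:
    """Evaluate the schedule at dried fraction ``nu`` in [0, 1].

    Non-increasing in nu, bounded between ``mu0 - delta`` and ``mu0``, with
    the logistic midpoint ``mu(nu_c) = mu0 - delta/2``.
    """
    if not (0.0 <= nu <= 1.0):
        raise ValueError(f"nu must be in [0, 1], got {nu}")
    if schedule.kind == "constant":
        return schedule.mu0
    return schedule.mu0 - schedule.delta * float(
        expit((nu - schedule.nu_c) / schedule.sigma)
    )
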