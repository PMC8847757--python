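"""Parameter container for the group-structured cooperation model.

All model constants live in a single frozen dataclass so that a simulation is
fully described by ``(SimulationParams, EnvironmentSchedule, seed)``.  The
defaults are the package's calibrated reference conditions (see
``docs/methods.md``): they make non-social populations persist in benign
environments (high ``R00``), collapse in harsh ones (low ``R00``), and let
cooperation rescue social populations in harsh environments when the
cooperation efficiency ``bK`` is high.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

#: The three population scenarios:
#: ``social``       - heritable cooperation degree, free evolution;
#: ``non_social``   - every individual is a free-rider (trait locked at 0);
#: ``non_structured`` - social trait dynamics but a single well-mixed group.
SCENARIOS = ("social", "non_social", "non_structured")

#: The 11 admissible cooperation degrees: 0.0 (free-rider) to 1.0.
DEFAULT_TRAIT_LEVELS = tuple(round(0.1 * k, 1) for k in range(11))


@dataclass(frozen=True)
class SimulationParams:
    """Every constant of the individual-based model.

    Parameters
    ----------
    R00 : float
        Baseline environmental resource availability (resource units).
    I : float
        Maximum resource increment rate: group resources saturate strictly
        below ``R0 * (1 + I)``.
    bK : float
        Cooperation efficiency — conversion from summed cooperation degree
        to group-resource benefit (resource units per unit degree).
    alpha : float
        Maximum per-individual reproductive rate (offspring per step).
    beta : float
        Fractional reproduction cost per unit cooperation degree,
        ``0 < beta <= 1``.
    M : float
        Metabolic consumption per individual per step (resource units).
    Ks : float
        Half-saturation constant for reproduction (resource units): the
        surplus ``s - M`` at which the reproductive rate is ``alpha/2``
        for a free-rider.
    c : float
        Newborn survival probability, ``0 < c <= 1``.
    age_standard : float
        Survival e-folding age (steps).
    m : float
        Per-offspring mutation probability.
    n_groups : int
        Number of group slots (patches); slots may be empty.
    N_init : int
        Initial population size.
    T : int
        Number of simulation steps.
    trait_levels : tuple of float
        The admissible cooperation degrees: exactly 11 equally spaced
        values within [0, 1].
    scenario : str
        One of :data:`SCENARIOS`.
    """

    R00: float = 4.0
    I: float = 5.0
    bK: float = 5.0
    alpha: float = 2.0
    beta: float = 0.5
    M: float = 1.0
    Ks: float = 1.0
    c: float = 0.9
    age_standard: float = 5.0
    m: float = 0.001
    n_groups: int = 90
    N_init: int = 300
    T: int = 10_000
    trait_levels: tuple = DEFAULT_TRAIT_LEVELS
    scenario: str = "social"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise InvalidParameterError(f"beta must be in (0, 1], got {self.beta}")
        if not 0.0 < self.c <= 1.0:
            raise InvalidParameterError(f"c must be in (0, 1], got {self.c}")
        if self.R00 <= 0:
            raise InvalidParameterError(f"R00 must be positive, got {self.R00}")
        if self.I <= 0:
            raise InvalidParameterError(f"I must be positive, got {self.I}")
        if self.bK < 0:
            raise InvalidParameterError(f"bK must be non-negative, got {self.bK}")
        if self.alpha <= 0:
            raise InvalidParameterError(f"alpha must be positive, got {self.alpha}")
        if self.M < 0:
            raise InvalidParameterError(f"M must be non-negative, got {self.M}")
        if self.Ks <= 0:
            raise InvalidParameterError(f"Ks must be positive, got {self.Ks}")
        if self.age_standard <= 0:
            raise InvalidParameterError(
                f"age_standard must be positive, got {self.age_standard}"
            )
        if not 0.0 <= self.m <= 1.0:
            raise InvalidParameterError(f"m must be in [0, 1], got {self.m}")
        if self.n_groups < 1:
            raise InvalidParameterError(f"n_groups must be >= 1, got {self.n_groups}")
        if self.N_init < 1:
            raise InvalidParameterError(f"N_init must be >= 1, got {self.N_init}")
        if self.T < 1:
            raise InvalidParameterError(f"T must be >= 1, got {self.T}")
        levels = np.asarray(self.trait_levels, dtype=float)
        if levels.size != 11:
            raise InvalidParameterError("trait_levels must hold exactly 11 values")
        if levels.min() < 0.0 or levels.max() > 1.0:
            raise InvalidParameterError("trait_levels must lie in [0, 1]")
        spacing = np.diff(levels)
        if np.any(spacing <= 0) or not np.allclose(spacing, spacing[0]):
            raise InvalidParameterError(
                "trait_levels must be strictly increasing and equally spaced"
            )
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        if self.scenario == "non_structured" and self.n_groups != 1:
            raise InvalidParameterError(
                "non_structured scenario requires n_groups == 1"
            )

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def levels(self) -> np.ndarray:
        """Trait levels as a float array."""
        return np.asarray(self.trait_levels, dtype=float)
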