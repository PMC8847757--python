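"""Deterministic micro-scenarios with hand-computed expected outcomes.

Each :class:`MicroScenario` freezes a tiny population, the exact RNG draws
the engine will consume (via :class:`~coopdyn.rng.ScriptedRng`), and the
next state worked out by hand from the model's kernels.  They make every
engine operation unit-testable bit-exactly; statistical realism is the job
of the property and Monte-Carlo tests, not of these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import PopulationState
from .params import SimulationParams
from .rng import ScriptedRng

__all__ = ["MicroScenario", "make_micro", "MICRO_NAMES"]

MICRO_NAMES = ("three_cooperators", "mixed_group", "starvation", "aging_cohort")


@dataclass
class MicroScenario:
    """A frozen micro-population plus scripted draws and expectations.

    ``expected`` holds hand-derived values: per-group resources and shares,
    per-member reproductive rates or survival probabilities, and the exact
    post-step state under the scripted draws.
    """

    name: str
    params: SimulationParams
    phi: tuple
    age: tuple
    gid: tuple
    R0_t: float
    uniforms: tuple
    integers: tuple
    poissons: tuple
    expected: dict = field(default_factory=dict)

    def state(self) -> PopulationState:
        return PopulationState(
            phi=np.array(self.phi, dtype=float),
            age=np.array(self.age, dtype=np.int64),
            gid=np.array(self.gid, dtype=np.int64),
            t=0,
            n_groups=self.params.n_groups,
        )

    def rng(self) -> ScriptedRng:
        return ScriptedRng(uniforms=self.uniforms, integers=self.integers,
                           poissons=self.poissons)


def _base(**kw) -> SimulationParams:
    kw.setdefault("m", 0.0)  # no mutation draws: keeps scripts hand-sized
    kw.setdefault("n_groups", 1)
    kw.setdefault("N_init", 3)
    kw.setdefault("T", 1)
    kw.setdefault("scenario", "social")
    return SimulationParams(**kw)


def make_micro(name: str) -> MicroScenario:
    """Return one of the frozen micro-scenarios by name."""
    if name == "three_cooperators":
        # Three full cooperators, R0 = 1, I = 5, bK = 5:
        #   benefit = 5 * 3 = 15; denom = 5*1/2 + 15 = 17.5
        #   R = 1 * (1 + 75/17.5) = 37/7 = 5.285714...
        #   s = (37/7)/3 = 37/21 = 1.761904...; surplus = 16/21
        #   F = 2 * (1 - 0.5*1.0) * (16/21)/(1 + 16/21) = 16/37 = 0.432432...
        # Scripted: offspring counts (1, 0, 2); dispersal all to slot 0;
        # survival (all at r = 0.9): parent draws (.5, .95, .2) kill parent 1,
        # newborn draws (.1, .89, .99) kill newborn 2 -> 2 deaths, N -> 4.
        return MicroScenario(
            name=name,
            params=_base(R00=1.0),
            phi=(1.0, 1.0, 1.0), age=(0, 0, 0), gid=(0, 0, 0), R0_t=1.0,
            poissons=(1, 0, 2), integers=(0, 0, 0),
            uniforms=(0.5, 0.95, 0.2, 0.1, 0.89, 0.99),
            expected={
                "R_group": 37.0 / 7.0,
                "share": 37.0 / 21.0,
                "rates": (16.0 / 37.0,) * 3,
                "births": 3, "deaths": 2, "N_next": 4,
                "phi_next": (1.0, 1.0, 1.0, 1.0),
                "age_next": (1, 1, 1, 1),
            },
        )
    if name == "mixed_group":
        # A free-rider (phi 0) and a half-cooperator (phi 0.5), R0 = 4:
        #   benefit = 5 * 0.5 = 2.5; denom = 5*4/2 + 2.5 = 12.5
        #   R = 4 * (1 + 12.5/12.5) = 8; s = 4; surplus = 3
        #   F_free = 2 * 1.00 * 3/4 = 1.5
        #   F_coop = 2 * 0.75 * 3/4 = 1.125
        #   ratio free/coop = 1/(1 - beta*phi) = 4/3 (the cost falls only on
        #   the cooperator; both enjoy the same share).
        # Scripted: one offspring each; everyone survives.
        return MicroScenario(
            name=name,
            params=_base(R00=4.0, N_init=2),
            phi=(0.0, 0.5), age=(0, 0), gid=(0, 0), R0_t=4.0,
            poissons=(1, 1), integers=(0, 0),
            uniforms=(0.0, 0.0, 0.0, 0.0),
            expected={
                "R_group": 8.0, "share": 4.0, "rates": (1.5, 1.125),
                "births": 2, "deaths": 0, "N_next": 4,
                "phi_next": (0.0, 0.5, 0.0, 0.5),
                "age_next": (1, 1, 1, 1),
            },
        )
    if name == "starvation":
        # Two free-riders on R0 = 1: share 0.5 <= M = 1, so both rates clamp
        # to 0 and no births occur.  Survival draws (.2, .99) at r = 0.9 kill
        # the second individual.
        return MicroScenario(
            name=name,
            params=_base(R00=1.0, N_init=2),
            phi=(0.0, 0.0), age=(0, 0), gid=(0, 0), R0_t=1.0,
            poissons=(0, 0), integers=(),
            uniforms=(0.2, 0.99),
            expected={
                "R_group": 1.0, "share": 0.5, "rates": (0.0, 0.0),
                "births": 0, "deaths": 1, "N_next": 1,
                "phi_next": (0.0,), "age_next": (1,),
            },
        )
    if name == "aging_cohort":
        # Free-riders aged 0, 5 and 10 with age_standard = 5: survival
        # probabilities c, c/e, c/e^2 = 0.9, 0.331091..., 0.121803...
        # Scripted: no births (Poisson 0s); draws (.85, .34, .05) kill the
        # age-5 individual only (0.34 > 0.9/e).
        c = 0.9
        return MicroScenario(
            name=name,
            params=_base(R00=8.0),
            phi=(0.0, 0.0, 0.0), age=(0, 5, 10), gid=(0, 0, 0), R0_t=8.0,
            poissons=(0, 0, 0), integers=(),
            uniforms=(0.85, 0.34, 0.05),
            expected={
                "survival": (c, c / np.e, c / np.e**2),
                "births": 0, "deaths": 1, "N_next": 2,
                "phi_next": (0.0, 0.0), "age_next": (1, 11),
            },
        )
    raise ValueError(f"unknown micro-scenario {name!r}; choose from {MICRO_NAMES}")
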