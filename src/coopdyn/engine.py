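"""The stochastic per-step lifecycle and the full-run driver.

One step executes, in this fixed order (matching the individual life cycle:
reproduction, dispersal, survival):

1. every occupied group produces resources (:func:`~coopdyn.model_core.group_resource`)
   and members take equal shares;
2. every individual draws a Poisson offspring count with mean equal to its
   reproductive rate;
3. each offspring inherits its parent's cooperation degree and may mutate;
4. offspring disperse to uniformly random group slots (empty slots included);
5. everyone — parents and this step's newborns alike — survives independently
   with the age-dependent probability, and survivors age by one step;
6. the step counter increments.

RNG draw order (the contract :class:`~coopdyn.rng.ScriptedRng` fixtures rely
on): (a) one Poisson draw per individual in state-array order; (b) one uniform
per offspring in parent order, only when mutation is active (``m > 0`` and the
scenario is not ``non_social``); (c) one integer per *mutated* offspring;
(d) one integer per offspring for dispersal; (e) one uniform per individual,
parents first then offspring, for survival.  Zero-size draws are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import model_core
from .environment import EnvironmentSchedule, constant, resource_at
from .params import SimulationParams
from .rng import RngStream, SeededRng

__all__ = [
    "Group",
    "PopulationState",
    "StepRecord",
    "ReplicateSeries",
    "initialize_population",
    "reproduce_group",
    "mutate_degree",
    "disperse",
    "apply_survival",
    "step",
    "run",
]

#: Column order of a series frame; kept stable so CSVs are byte-reproducible.
SERIES_COLUMNS = [
    "t",
    "R0_t",
    "N",
    "n_cooperators",
    "prop_coop",
    "mean_degree",
    "births",
    "deaths",
]

GROUP_COLUMNS = [
    "t",
    "group_id",
    "size",
    "sum_phi",
    "R_group",
    "total_offspring",
    "per_capita_offspring",
]


@dataclass
class Group:
    """A view of one group's members (used by per-group operations)."""

    phi: np.ndarray
    age: np.ndarray

    @property
    def size(self) -> int:
        return len(self.phi)

    @property
    def sum_phi(self) -> float:
        return float(self.phi.sum())


@dataclass
class PopulationState:
    """All individuals, stored as parallel arrays, plus the step counter.

    ``gid[i]`` is individual ``i``'s group slot in ``[0, n_groups)``.  The
    number of slots never changes during a run; slots may be empty and can
    be recolonized by dispersing offspring.
    """

    phi: np.ndarray
    age: np.ndarray
    gid: np.ndarray
    t: int
    n_groups: int

    @property
    def N(self) -> int:
        return len(self.phi)

    def group(self, g: int) -> Group:
        mask = self.gid == g
        return Group(phi=self.phi[mask], age=self.age[mask])

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.gid, minlength=self.n_groups)

    def group_sum_phi(self) -> np.ndarray:
        return np.bincount(self.gid, weights=self.phi, minlength=self.n_groups)


@dataclass(frozen=True)
class StepRecord:
    """Per-step observables.

    Reproductive outputs (``births``) are recorded before survival;
    population-level observables (``N``, cooperator fraction, mean degree)
    after survival.  ``mean_degree`` and ``prop_coop`` are 0 when ``N`` is 0.
    """

    t: int
    R0_t: float
    N: int
    n_cooperators: int
    prop_coop: float
    mean_degree: float
    births: int
    deaths: int


@dataclass
class ReplicateSeries:
    """One full run: a per-step frame plus optional per-group snapshots."""

    frame: pd.DataFrame
    params: SimulationParams
    schedule: EnvironmentSchedule
    seed: Optional[int] = None
    snapshots: Optional[pd.DataFrame] = None

    @property
    def extinct(self) -> bool:
        return bool((self.frame["N"] == 0).any())


def initialize_population(params: SimulationParams, rng: RngStream) -> PopulationState:
    """Create the step-0 population.

    ``N_init`` individuals are assigned uniformly at random to the
    ``n_groups`` slots (one group-slot integer per individual, then — for
    social and non_structured scenarios — one trait-level integer per
    individual).  Non-social populations start, and stay, all free-riders.
    All ages are 0.
    """
    n = params.N_init
    gid = np.asarray(rng.integers(0, params.n_groups, size=n), dtype=np.int64)
    if params.scenario == "non_social":
        phi = np.zeros(n)
    else:
        idx = np.asarray(rng.integers(0, len(params.trait_levels), size=n))
        phi = params.levels[idx]
    return PopulationState(
        phi=phi, age=np.zeros(n, dtype=np.int64), gid=gid, t=0,
        n_groups=params.n_groups,
    )


def reproduce_group(group: Group, R_group: float, params: SimulationParams,
                    rng: RngStream) -> np.ndarray:
    """Offspring counts for one group's members, in member order.

    Each member's count is Poisson with mean equal to its reproductive rate
    at the equal share ``R_group / size``; the expected total is the sum of
    the members' rates.
    """
    s = model_core.per_capita_share(R_group, group.size)
    rates = model_core.reproductive_rate(
        params.alpha, params.beta, group.phi, np.full(group.size, s),
        params.M, params.Ks,
    )
    return np.asarray(rng.poisson(rates), dtype=np.int64)


def mutate_degree(phi_parent: float, m: float, params: SimulationParams,
                  rng: RngStream) -> float:
    """Offspring trait after possible mutation (scalar form).

    With probability ``1 - m`` the parent's degree is inherited unchanged;
    with probability ``m`` a level is redrawn uniformly from the 11-level
    grid (possibly equal to the parent's).  Non-social populations are
    locked at 0 and consume no draws.
    """
    if params.scenario == "non_social":
        return 0.0
    if m > 0 and rng.uniform() < m:
        return float(params.levels[rng.integers(0, len(params.trait_levels))])
    return float(phi_parent)


def _mutate_offspring(off_phi: np.ndarray, params: SimulationParams,
                      rng: RngStream) -> np.ndarray:
    """Vectorized mutation pass used by :func:`step` (same kernel as
    :func:`mutate_degree`, same draw order)."""
    if params.scenario == "non_social" or params.m == 0.0 or off_phi.size == 0:
        return off_phi
    u = np.asarray(rng.uniform(size=off_phi.size))
    mutate = u < params.m
    n_mut = int(mutate.sum())
    if n_mut:
        idx = np.asarray(rng.integers(0, len(params.trait_levels), size=n_mut))
        off_phi = off_phi.copy()
        off_phi[mutate] = params.levels[idx]
    return off_phi


def disperse(n_offspring: int, n_groups: int, rng: RngStream) -> np.ndarray:
    """Uniform group-slot assignment for this step's offspring.

    Every slot — occupied or empty — is equally likely; there is no
    natal-patch bias (the model has no explicit spatial structure).
    """
    if n_offspring == 0:
        return np.empty(0, dtype=np.int64)
    return np.asarray(rng.integers(0, n_groups, size=n_offspring), dtype=np.int64)


def apply_survival(state: PopulationState, params: SimulationParams,
                   rng: RngStream) -> tuple[PopulationState, int]:
    """Independent age-dependent survival; survivors age by one step.

    Newborns (age 0) face survival probability exactly ``c``.  Returns the
    post-survival state and the number of deaths.
    """
    n = state.N
    if n == 0:
        return state, 0
    r = model_core.survival_probability(params.c, state.age, params.age_standard)
    u = np.asarray(rng.uniform(size=n))
    alive = u < r
    deaths = int(n - alive.sum())
    new = PopulationState(
        phi=state.phi[alive],
        age=state.age[alive] + 1,
        gid=state.gid[alive],
        t=state.t,
        n_groups=state.n_groups,
    )
    return new, deaths


def _record(state: PopulationState, R0_t: float, births: int, deaths: int,
            t: int) -> StepRecord:
    n = state.N
    if n:
        n_coop = int((state.phi > 0).sum())
        prop = n_coop / n
        mean_deg = float(state.phi.mean())
    else:
        n_coop, prop, mean_deg = 0, 0.0, 0.0
    return StepRecord(t=t, R0_t=float(R0_t), N=n, n_cooperators=n_coop,
                      prop_coop=prop, mean_degree=mean_deg,
                      births=int(births), deaths=int(deaths))


def step(state: PopulationState, R0_t: float, params: SimulationParams,
         rng: RngStream, snapshot: bool = False):
    """Advance the population one step.

    Returns ``(new_state, record, group_rows)`` where ``group_rows`` is a
    list of per-group tuples (see ``GROUP_COLUMNS``) when ``snapshot`` is
    true, else ``None``.  An extinct population (N = 0) is absorbing: the
    step only increments ``t`` and records zeros.
    """
    t = state.t
    if state.N == 0:
        empty = PopulationState(phi=state.phi, age=state.age, gid=state.gid,
                                t=t + 1, n_groups=state.n_groups)
        rows = [] if snapshot else None
        return empty, _record(empty, R0_t, 0, 0, t), rows

    sizes = state.group_sizes()
    sum_phi = state.group_sum_phi()
    occupied = sizes > 0
    R = np.empty(state.n_groups)
    R[occupied] = model_core.group_resource(R0_t, params.I, params.bK,
                                            sum_phi[occupied])
    # Equal sharing: each individual's consumption is its group's pool over
    # its group's size.
    share = R[state.gid] / sizes[state.gid]
    rates = model_core.reproductive_rate(params.alpha, params.beta, state.phi,
                                         share, params.M, params.Ks)
    counts = np.asarray(rng.poisson(rates), dtype=np.int64)
    births = int(counts.sum())

    off_phi = np.repeat(state.phi, counts)
    off_phi = _mutate_offspring(off_phi, params, rng)
    off_gid = disperse(births, state.n_groups, rng)

    rows = None
    if snapshot:
        rows = []
        per_group_off = np.bincount(state.gid, weights=counts,
                                    minlength=state.n_groups)
        for g in np.flatnonzero(occupied):
            rows.append((t, int(g), int(sizes[g]), float(sum_phi[g]),
                         float(R[g]), int(per_group_off[g]),
                         float(per_group_off[g] / sizes[g])))

    merged = PopulationState(
        phi=np.concatenate([state.phi, off_phi]),
        age=np.concatenate([state.age, np.zeros(births, dtype=np.int64)]),
        gid=np.concatenate([state.gid, off_gid]),
        t=t,
        n_groups=state.n_groups,
    )
    survived, deaths = apply_survival(merged, params, rng)
    survived.t = t + 1
    return survived, _record(survived, R0_t, births, deaths, t), rows


def run(params: SimulationParams,
        schedule: Optional[EnvironmentSchedule] = None,
        rng: Optional[RngStream] = None,
        seed: Optional[int] = None,
        snapshot_steps: Sequence[int] = ()) -> ReplicateSeries:
    """Simulate ``params.T`` steps and return the per-step series.

    Deterministic given ``(params, schedule, seed)``.  After extinction the
    series continues with N = 0 rows so all replicates share one length.

    Parameters
    ----------
    schedule : EnvironmentSchedule, optional
        Defaults to a constant environment at ``params.R00``.
    rng, seed :
        Pass either an :class:`~coopdyn.rng.RngStream` or a seed (default
        seed 0).
    snapshot_steps :
        Steps at which a per-group table (size, sum_phi, resources,
        reproductive output) is recorded.
    """
    if schedule is None:
        schedule = constant(params.R00)
    if rng is None:
        rng = SeededRng(0 if seed is None else seed)
        used_seed = rng.seed
    else:
        used_seed = getattr(rng, "seed", None)
    snap = frozenset(int(s) for s in snapshot_steps)

    state = initialize_population(params, rng)
    records = []
    group_rows: list = []
    for t in range(params.T):
        R0_t = resource_at(schedule, t)
        state, rec, rows = step(state, R0_t, params, rng, snapshot=t in snap)
        records.append(rec)
        if rows:
            group_rows.extend(rows)

    frame = pd.DataFrame(records, columns=SERIES_COLUMNS)
    snapshots = (pd.DataFrame(group_rows, columns=GROUP_COLUMNS)
                 if snap else None)
    return ReplicateSeries(frame=frame, params=params, schedule=schedule,
                           seed=used_seed, snapshots=snapshots)
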