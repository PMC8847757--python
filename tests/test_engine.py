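"""Stochastic lifecycle: seeded determinism, bookkeeping, Monte-Carlo
checks of each randomized stage."""

import numpy as np
import pytest
from scipy import stats

from coopdyn import (SimulationParams, SeededRng, apply_survival, disperse,
                     initialize_population, mutate_degree, run, step)
from coopdyn.engine import Group, PopulationState, reproduce_group
from coopdyn.rng import ScriptedRng


def small_params(**kw):
    kw.setdefault("T", 50)
    kw.setdefault("N_init", 60)
    kw.setdefault("n_groups", 10)
    return SimulationParams(**kw)


class TestInitialize:
    def test_size_and_ages(self):
        p = SimulationParams()
        state = initialize_population(p, SeededRng(1))
        assert state.N == 300
        assert state.n_groups == 90
        assert np.all(state.age == 0)
        assert np.all((0 <= state.gid) & (state.gid < 90))
        assert state.t == 0

    def test_non_social_starts_all_free_riders(self):
        p = SimulationParams(scenario="non_social")
        state = initialize_population(p, SeededRng(2))
        assert np.all(state.phi == 0.0)

    def test_non_structured_single_group(self):
        p = SimulationParams(scenario="non_structured", n_groups=1)
        state = initialize_population(p, SeededRng(3))
        assert np.all(state.gid == 0)

    def test_seeded_determinism(self):
        p = small_params(N_init=12, n_groups=4)
        a = initialize_population(p, SeededRng(7))
        b = initialize_population(p, SeededRng(7))
        assert np.array_equal(a.gid, b.gid) and np.array_equal(a.phi, b.phi)

    def test_social_traits_on_grid(self):
        p = SimulationParams()
        state = initialize_population(p, SeededRng(4))
        assert set(np.round(state.phi, 1)) <= set(p.trait_levels)


class TestReproduceGroup:
    def test_starved_members_never_reproduce(self):
        p = small_params(R00=1.0)
        group = Group(phi=np.zeros(4), age=np.zeros(4, dtype=np.int64))
        # share 0.25 <= M = 1 -> all rates 0 -> Poisson(0) is identically 0
        counts = reproduce_group(group, 1.0, p, SeededRng(5))
        assert counts.sum() == 0

    def test_poisson_mean_matches_rates(self):
        """Three members at rate 0.5 each -> mean total offspring 1.5."""
        p = small_params(alpha=2.0, beta=0.5, M=1.0, Ks=1.0)
        # free-riders with share s: rate = 2 (s-1)/(1 + (s-1)) = 0.5 at s = 4/3
        group = Group(phi=np.zeros(3), age=np.zeros(3, dtype=np.int64))
        rng = SeededRng(6)
        totals = [reproduce_group(group, 4.0, p, rng).sum() for _ in range(10_000)]
        se = np.sqrt(1.5 / 10_000)
        assert np.mean(totals) == pytest.approx(1.5, abs=3 * se)

    def test_scripted_counts_pass_through(self):
        p = small_params()
        group = Group(phi=np.full(3, 0.5), age=np.zeros(3, dtype=np.int64))
        counts = reproduce_group(group, 8.0, p, ScriptedRng(poissons=(2, 0, 1)))
        assert counts.tolist() == [2, 0, 1]


class TestMutation:
    def test_zero_rate_is_identity(self):
        p = small_params(m=0.0)
        rng = SeededRng(8)
        assert all(mutate_degree(0.3, 0.0, p, rng) == 0.3 for _ in range(100))

    def test_certain_mutation_is_uniform_over_levels(self):
        """m = 1: every level drawn with frequency 1/11."""
        from coopdyn.engine import _mutate_offspring

        p = small_params(m=1.0)
        off = _mutate_offspring(np.full(100_000, 0.7), p, SeededRng(9))
        freqs = np.array([(np.isclose(off, lv)).mean() for lv in p.trait_levels])
        se = np.sqrt((1 / 11) * (10 / 11) / 100_000)
        assert np.all(np.abs(freqs - 1 / 11) < 3.5 * se)

    def test_non_social_trait_locked(self):
        p = small_params(scenario="non_social", m=1.0)
        rng = ScriptedRng()  # must consume no draws
        assert mutate_degree(0.9, 1.0, p, rng) == 0.0


class TestDisperse:
    def test_single_group(self):
        assert np.all(disperse(25, 1, SeededRng(10)) == 0)

    def test_uniform_over_slots(self):
        counts = np.bincount(disperse(100_000, 90, SeededRng(11)), minlength=90)
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-3

    def test_no_offspring(self):
        assert disperse(0, 90, ScriptedRng()).size == 0


class TestSurvival:
    def test_newborn_cohort_survives_at_rate_c(self):
        p = small_params(c=0.9)
        state = PopulationState(phi=np.zeros(10_000),
                                age=np.zeros(10_000, dtype=np.int64),
                                gid=np.zeros(10_000, dtype=np.int64),
                                t=0, n_groups=1)
        new, deaths = apply_survival(state, p, SeededRng(12))
        se = np.sqrt(10_000 * 0.9 * 0.1)
        assert new.N == pytest.approx(9000, abs=3 * se)
        assert deaths == 10_000 - new.N

    def test_survivors_age_by_exactly_one(self):
        p = small_params(c=1.0, age_standard=1e9)
        ages = np.array([0, 3, 7], dtype=np.int64)
        state = PopulationState(phi=np.zeros(3), age=ages.copy(),
                                gid=np.zeros(3, dtype=np.int64), t=0, n_groups=1)
        new, deaths = apply_survival(state, p, SeededRng(13))
        assert deaths == 0
        assert np.array_equal(new.age, ages + 1)

    def test_scripted_deaths(self):
        p = small_params(c=0.9)
        state = PopulationState(phi=np.zeros(3),
                                age=np.zeros(3, dtype=np.int64),
                                gid=np.zeros(3, dtype=np.int64), t=0, n_groups=1)
        # draws over/under r = 0.9 select exactly who dies
        new, deaths = apply_survival(state, p, ScriptedRng(uniforms=(0.95, 0.1, 0.91)))
        assert deaths == 2 and new.N == 1


class TestStepAndRun:
    def test_population_bookkeeping_exact(self):
        """N_t = N_{t-1} + births_t - deaths_t at every step."""
        p = small_params(T=200, R00=4.0, N_init=100, n_groups=20)
        series = run(p, seed=21).frame
        n_prev = p.N_init
        for _, row in series.iterrows():
            assert row["N"] == n_prev + row["births"] - row["deaths"]
            n_prev = row["N"]

    def test_trait_closure_without_mutation(self):
        """With m = 0 no trait value can appear de novo."""
        p = small_params(T=1, m=0.0, R00=4.0, N_init=80, n_groups=10)
        rng = SeededRng(22)
        state = initialize_population(p, rng)
        present = set(np.round(state.phi, 1))
        from coopdyn.environment import constant, resource_at
        sched = constant(p.R00)
        for t in range(200):
            state, _, _ = step(state, resource_at(sched, t), p, rng)
            assert set(np.round(state.phi, 1)) <= present

    def test_group_count_constant_and_gids_valid(self):
        p = small_params(T=100)
        rng = SeededRng(23)
        state = initialize_population(p, rng)
        for t in range(100):
            state, _, _ = step(state, 4.0, p, rng)
            assert state.n_groups == p.n_groups
            if state.N:
                assert state.gid.max() < p.n_groups

    def test_extinction_is_absorbing(self):
        state = PopulationState(phi=np.empty(0), age=np.empty(0, dtype=np.int64),
                                gid=np.empty(0, dtype=np.int64), t=5, n_groups=3)
        p = small_params()
        new, rec, _ = step(state, 4.0, p, SeededRng(24))
        assert new.N == 0 and rec.N == 0 and rec.births == 0 and new.t == 6

    def test_run_reproducible_and_seed_sensitive(self):
        p = small_params(T=60)
        a = run(p, seed=31).frame
        b = run(p, seed=31).frame
        c = run(p, seed=32).frame
        assert a.equals(b)
        assert not a.equals(c)

    def test_run_length_and_extinction_padding(self):
        p = small_params(T=80, R00=1.0, scenario="non_social")
        series = run(p, seed=33)
        assert len(series.frame) == 80
        assert series.extinct
        assert (series.frame["N"].iloc[-1] == 0)
        # once N hits zero it stays zero
        n = series.frame["N"].to_numpy()
        first_zero = int(np.argmax(n == 0))
        assert np.all(n[first_zero:] == 0)

    def test_non_social_run_reports_zero_cooperation(self):
        p = small_params(T=100, R00=8.0, scenario="non_social")
        frame = run(p, seed=34).frame
        assert (frame["prop_coop"] == 0).all()
        assert (frame["mean_degree"] == 0).all()

    def test_snapshot_table_matches_resource_model(self):
        from coopdyn.model_core import group_resource

        p = small_params(T=3, N_init=40, n_groups=5)
        series = run(p, seed=35, snapshot_steps=[0, 2])
        snaps = series.snapshots
        assert set(snaps["t"]) <= {0, 2}
        for _, row in snaps.iterrows():
            assert row["R_group"] == pytest.approx(
                group_resource(p.R00, p.I, p.bK, row["sum_phi"]))
            assert row["per_capita_offspring"] == pytest.approx(
                row["total_offspring"] / row["size"])
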