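"""The lottery update: fitness-weighted deaths and vacancy refilling."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from moveflora.dynamics import DynamicsParams, fill_vacancies, select_deaths, step
from moveflora.pools import Community, initialize_community
from moveflora.selection import SelectionParams, env_fitness

from _oracles import _death_vector_probs, enumerate_step_distribution
from conftest import make_pool


def com(ids, traits, counts):
    return Community(
        np.array(ids, dtype=object), np.array(traits, float), np.array(counts)
    )


class TestDynamicsParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"death_fraction": 0.0},
            {"death_fraction": 1.5},
            {"immigration_rate": -0.1},
            {"immigration_rate": 1.1},
            {"death_floor": 0.0},
            {"pool_weighting": "nope"},
            {"recruit_weighting": "nope"},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            DynamicsParams(**kwargs)


class TestSelectDeaths:
    def test_equal_fitness_gives_uniform_death_weights(self, rng):
        c = com(["a", "b"], [0.2, 0.8], [3000, 3000])
        params = DynamicsParams(death_fraction=0.1)
        _, deaths = select_deaths(c, np.array([1.0, 1.0]), params, rng)
        assert deaths.sum() == 600
        # symmetric weights: per-species death counts ~ Binomial(600, 1/2)
        assert abs(deaths[0] - 300) < 5 * math.sqrt(600 * 0.25)

    def test_weight_ratio_between_fit_and_unfit(self):
        # relative fitness 1.0 vs 0.05 at floor 0.05 -> weights 0.05 vs ~1.0
        params = DynamicsParams(death_fraction=0.5, death_floor=0.05)
        f = np.array([1.0, 0.05])
        w = 1.0 - f / f.max() + params.death_floor
        assert w[0] == pytest.approx(0.05)
        assert w[1] == pytest.approx(1.0)
        # empirically, per-individual death odds follow that 1:20 ratio
        c = com(["fit", "unfit"], [0.3, 0.7], [2000, 2000])
        rng = np.random.default_rng(0)
        _, deaths = select_deaths(c, f, params, rng)
        # expected deaths of "fit": 2000 slots but weight share 0.05/1.05
        assert deaths[1] > deaths[0]

    def test_total_extinction_rejected(self, rng):
        c = com(["a"], [0.5], [10])
        with pytest.raises(ValueError, match="extinguish"):
            select_deaths(c, np.array([1.0]), DynamicsParams(death_fraction=1.0), rng)

    def test_nonpositive_fitness_rejected(self, rng):
        c = com(["a", "b"], [0.2, 0.8], [5, 5])
        with pytest.raises(ValueError, match="positive"):
            select_deaths(c, np.array([1.0, 0.0]), DynamicsParams(), rng)

    def test_death_counts_match_exhaustive_enumeration(self):
        # J=6, S=2, K=3: compare sampled death vectors to the exact
        # successive-weighted-sampling distribution
        counts = (4, 2)
        fitness = np.array([1.0, 0.4])
        params = DynamicsParams(death_fraction=0.5, death_floor=0.05)
        weights = tuple(1.0 - fitness / fitness.max() + params.death_floor)
        exact = _death_vector_probs(counts, weights, K=3)

        c = com(["a", "b"], [0.3, 0.6], list(counts))
        rng = np.random.default_rng(777)
        observed: dict[tuple, int] = {}
        n = 40_000
        for _ in range(n):
            _, deaths = select_deaths(c, fitness, params, rng)
            key = tuple(deaths.tolist())
            observed[key] = observed.get(key, 0) + 1
        states = sorted(exact)
        f_obs = [observed.get(s, 0) for s in states]
        f_exp = [exact[s] * n for s in states]
        assert chisquare(f_obs, f_exp).pvalue > 0.001


class TestFillVacancies:
    def test_closed_community_gains_no_species(self, rng):
        c = com(["a", "b", "c"], [0.2, 0.5, 0.8], [5, 3, 0])
        pool = make_pool(["a", "b", "c"], [0.2, 0.5, 0.8], [0.3, 0.3, 0.4])
        dyn = DynamicsParams(immigration_rate=0.0)
        out = fill_vacancies(c, pool, 0.4, SelectionParams(), dyn, K=4, rng=rng)
        assert out.size == 12
        assert out.counts[2] == 0  # absent species cannot enter locally

    def test_full_immigration_from_single_species_pool(self, rng):
        c = com(["a", "b"], [0.2, 0.8], [5, 3])
        pool = make_pool(["b"], [0.8], [1.0])
        # community table must contain all pool species; "b" is shared
        dyn = DynamicsParams(immigration_rate=1.0)
        out = fill_vacancies(c, pool, 0.8, SelectionParams(), dyn, K=10, rng=rng)
        assert out.counts[1] == 3 + 10

    def test_local_recruitment_probabilities_match_hand_computation(self):
        # counts 5/3/2 at traits 0.2/0.5/0.8, env 0.4, sigma 0.2, no
        # competition: local weights are count * exp(-(t-0.4)^2/0.08)
        c = com(["a", "b", "c"], [0.2, 0.5, 0.8], [5, 3, 2])
        pool = make_pool(["a", "b", "c"], [0.2, 0.5, 0.8], [1 / 3, 1 / 3, 1 / 3])
        sel = SelectionParams(sigma_env=0.2, comp_strength=0.0)
        dyn = DynamicsParams(immigration_rate=0.0, recruit_weighting="fitness")
        w = np.array([5, 3, 2]) * np.array(
            [math.exp(-0.5), math.exp(-0.125), math.exp(-2.0)]
        )
        p = w / w.sum()
        n = 50_000
        rng = np.random.default_rng(5)
        out = fill_vacancies(c, pool, 0.4, sel, dyn, K=n, rng=rng)
        freq = (out.counts - c.counts) / n
        assert np.all(np.abs(freq - p) < 5 * np.sqrt(p * (1 - p) / n))

    def test_pool_recruitment_weights_abundance_times_fitness(self):
        c = com(["a", "b", "c"], [0.2, 0.5, 0.8], [5, 3, 2])
        pool = make_pool(["a", "b", "c"], [0.2, 0.5, 0.8], [0.5, 0.3, 0.2])
        sel = SelectionParams(sigma_env=0.2, comp_strength=0.0)
        dyn = DynamicsParams(immigration_rate=1.0, recruit_weighting="fitness")
        w = np.array([0.5, 0.3, 0.2]) * np.array(
            [math.exp(-0.5), math.exp(-0.125), math.exp(-2.0)]
        )
        p = w / w.sum()
        n = 50_000
        out = fill_vacancies(c, pool, 0.4, sel, dyn, K=n, rng=np.random.default_rng(6))
        freq = (out.counts - c.counts) / n
        assert np.all(np.abs(freq - p) < 5 * np.sqrt(p * (1 - p) / n))

    def test_neutral_mode_ignores_fitness(self):
        c = com(["a", "b"], [0.0, 1.0], [9, 1])
        pool = make_pool(["a", "b"], [0.0, 1.0], [0.5, 0.5])
        dyn = DynamicsParams(immigration_rate=0.0, recruit_weighting="neutral")
        n = 30_000
        out = fill_vacancies(c, pool, 1.0, SelectionParams(), dyn, K=n,
                             rng=np.random.default_rng(7))
        freq = (out.counts[0] - 9) / n
        assert abs(freq - 0.9) < 5 * math.sqrt(0.9 * 0.1 / n)

    def test_vanishing_weights_fall_back_to_uniform_with_warning(self, caplog):
        c = com(["a", "b"], [0.0, 0.05], [5, 5])
        pool = make_pool(["a", "b"], [0.0, 0.05], [0.5, 0.5])
        sel = SelectionParams(sigma_env=0.001)  # fitness underflows at env=1
        dyn = DynamicsParams(immigration_rate=1.0, recruit_weighting="fitness")
        with caplog.at_level("WARNING", logger="moveflora.dynamics"):
            out = fill_vacancies(c, pool, 1.0, sel, dyn, K=10,
                                 rng=np.random.default_rng(8))
        assert out.size == 20
        assert any("uniform" in r.message for r in caplog.records)


class TestStep:
    def test_conservation_over_many_steps(self, small_pool, rng):
        c = initialize_community(small_pool, 200, seed=1)
        sel, dyn = SelectionParams(), DynamicsParams()
        for _ in range(300):
            c = step(c, small_pool, 0.4, sel, dyn, rng)
            assert c.size == 200

    def test_fixed_seed_reproduces_trajectory(self, small_pool):
        sel, dyn = SelectionParams(), DynamicsParams()

        def run():
            rng = np.random.default_rng(99)
            c = initialize_community(small_pool, 300, seed=2)
            for _ in range(50):
                c = step(c, small_pool, 0.35, sel, dyn, rng)
            return c.counts

        assert np.array_equal(run(), run())

    def test_forced_takeover_by_pool_species(self):
        # m=1 with a single-species pool at the optimum: near-total
        # replacement drives the community to monodominance in a few steps
        c = com(["a", "b"], [0.1, 0.4], [50, 0])
        pool = make_pool(["b"], [0.4], [1.0])
        sel = SelectionParams(sigma_env=0.05)
        dyn = DynamicsParams(death_fraction=0.9, immigration_rate=1.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            c = step(c, pool, 0.4, sel, dyn, rng)
        assert c.size == 50
        assert c.counts[0] == 0 and c.counts[1] == 50

    def test_one_step_distribution_matches_exhaustive_enumeration(self):
        """Full transition distribution on J=6, S=3 vs exact enumeration."""
        counts = (3, 2, 1)
        traits = (0.2, 0.5, 0.8)
        pool_ab = (0.5, 0.3, 0.2)
        env, m = 0.45, 0.3
        sel = SelectionParams(sigma_env=0.2, sigma_comp=0.3, comp_strength=0.5)
        dyn = DynamicsParams(death_fraction=0.5, immigration_rate=m,
                             recruit_weighting="fitness")
        exact = enumerate_step_distribution(
            counts, traits, pool_ab, env,
            sel.sigma_env, sel.sigma_comp, sel.comp_strength,
            dyn.death_fraction, m, dyn.death_floor, "fitness",
        )
        assert sum(exact.values()) == pytest.approx(1.0, abs=1e-9)

        c = com(["a", "b", "c"], traits, counts)
        pool = make_pool(["a", "b", "c"], traits, pool_ab)
        rng = np.random.default_rng(4242)
        n = 30_000
        observed: dict[tuple, int] = {}
        for _ in range(n):
            out = step(c, pool, env, sel, dyn, rng)
            key = tuple(out.counts.tolist())
            observed[key] = observed.get(key, 0) + 1

        # pool rare states so every expected bin is adequately filled
        common = [s for s in exact if exact[s] * n >= 10]
        rest = 1.0 - sum(exact[s] for s in common)
        f_obs = [observed.get(s, 0) for s in common]
        f_obs.append(n - sum(f_obs))
        f_exp = [exact[s] * n for s in common] + [rest * n]
        assert chisquare(f_obs, f_exp).pvalue > 0.001

    def test_neutral_limit_is_a_martingale(self, small_pool):
        """Equal fitnesses, closed community: expected abundance change 0."""
        sel = SelectionParams(sigma_env=1e6, comp_strength=0.0)
        dyn = DynamicsParams(death_fraction=0.2, immigration_rate=0.0)
        c0 = initialize_community(small_pool, 200, seed=6)
        rng = np.random.default_rng(11)
        reps = 2000
        drifts = np.zeros((reps, len(small_pool)))
        for r in range(reps):
            out = step(c0, small_pool, 0.5, sel, dyn, rng)
            drifts[r] = out.counts - c0.counts
        mean = drifts.mean(axis=0)
        se = drifts.std(axis=0, ddof=1) / np.sqrt(reps)
        present = c0.counts > 0
        assert np.all(np.abs(mean[present]) < 3 * se[present])
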