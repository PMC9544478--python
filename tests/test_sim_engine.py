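"""Unit and property tests for the single-locus drought-selection simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onsen_fate.sim_engine import (
    DROUGHT,
    HET,
    NO_DROUGHT,
    NORMAL,
    TE_HOM,
    WT_HOM,
    DroughtSchedule,
    PopulationState,
    SimParams,
    build_drought_schedule,
    exact_chain_distribution,
    genotype_fitness,
    initialize_population,
    next_generation,
    run_grid,
    run_replicate,
    run_replicates,
)


class TestDroughtSchedule:
    def test_single_short_event_centred(self):
        s = build_drought_schedule(50, 1, 2)
        assert s.drought_generations == frozenset({25, 26})

    def test_two_events_of_three_generations(self):
        s = build_drought_schedule(50, 2, 3)
        assert s.drought_generations == frozenset({17, 18, 19, 33, 34, 35})

    def test_four_long_events_are_disjoint_blocks(self):
        # enumerated starts: round(e*50/5) = 10, 20, 30, 40
        s = build_drought_schedule(50, 4, 4)
        expected = frozenset(
            g for start in (10, 20, 30, 40) for g in range(start, start + 4)
        )
        assert s.drought_generations == expected
        assert len(s.drought_generations) == 16

    def test_events_not_fitting_rejected(self):
        with pytest.raises(ValueError):
            build_drought_schedule(5, 3, 2)

    def test_overlapping_placement_rejected(self):
        # G=8 with 3 events of length 2: starts 2, 4, 6 touch but do not
        # overlap; G=7 forces an overlap
        with pytest.raises(ValueError):
            build_drought_schedule(7, 3, 2)

    @settings(max_examples=200, deadline=None)
    @given(
        generations=st.integers(20, 200),
        n_events=st.integers(1, 4),
        event_length=st.sampled_from([2, 3, 4]),
    )
    def test_schedule_blocks_within_horizon_and_disjoint(
        self, generations, n_events, event_length
    ):
        try:
            s = build_drought_schedule(generations, n_events, event_length)
        except ValueError:
            return
        gens = sorted(s.drought_generations)
        assert len(gens) == n_events * event_length
        assert gens[0] >= 1 and gens[-1] <= generations


class TestFitness:
    def test_strong_drought_advantage(self):
        p = SimParams(s_plus=5.0)
        assert genotype_fitness(TE_HOM, DROUGHT, p) == 6.0

    @pytest.mark.parametrize("condition", [DROUGHT, NORMAL])
    def test_heterozygote_neutral_when_recessive(self, condition):
        p = SimParams(s_plus=5.0, s_minus=-0.9)
        assert genotype_fitness(HET, condition, p) == 1.0

    def test_near_lethal_normal_penalty(self):
        p = SimParams(s_minus=-0.9)
        assert genotype_fitness(TE_HOM, NORMAL, p) == pytest.approx(0.1)

    def test_wild_type_is_reference(self):
        assert genotype_fitness(WT_HOM, DROUGHT, SimParams(s_plus=5.0)) == 1.0

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            SimParams(s_minus=-1.5)


class TestInitialization:
    def test_single_carrier_among_hundred(self):
        st_ = initialize_population(SimParams())
        assert (st_.n_wt_hom, st_.n_het, st_.n_te_hom) == (99, 1, 0)
        assert st_.allele_frequency == pytest.approx(0.005)
        assert 2 * st_.pop_size == 200

    def test_single_founder_is_carrier(self):
        st_ = initialize_population(SimParams(carrying_capacity=1))
        assert (st_.n_wt_hom, st_.n_het, st_.n_te_hom) == (0, 1, 0)
        assert st_.allele_frequency == 0.5

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            SimParams(carrying_capacity=0)


class TestNextGeneration:
    def test_all_wild_type_stays_at_capacity(self, rng):
        p = SimParams(s_plus=2.0, s_minus=-0.5)
        st_ = PopulationState(0, 100, 0, 0)
        nxt = next_generation(st_, DROUGHT, p, rng)
        assert (nxt.n_wt_hom, nxt.n_het, nxt.n_te_hom) == (100, 0, 0)

    def test_hard_selection_halves_population(self, rng):
        p = SimParams(s_minus=-0.5)
        st_ = PopulationState(0, 0, 0, 100)
        nxt = next_generation(st_, NORMAL, p, rng)
        assert nxt.pop_size == 50
        assert nxt.n_te_hom == 50

    def test_extinct_population_cannot_reproduce(self, rng):
        with pytest.raises(ValueError):
            next_generation(PopulationState(0, 0, 0, 0), NORMAL, SimParams(), rng)

    def test_selfed_heterozygote_segregates_mendelian(self, rng):
        # a lone selfing heterozygote: offspring 1:2:1 over genotypes
        p = SimParams(carrying_capacity=1, selfing_rate=1.0)
        counts = np.zeros(3)
        st_ = PopulationState(0, 0, 1, 0)
        for _ in range(20_000):
            nxt = next_generation(st_, NORMAL, p, rng)
            counts += (nxt.n_wt_hom, nxt.n_het, nxt.n_te_hom)
        freqs = counts / counts.sum()
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.015)

    def test_pop_size_never_exceeds_capacity(self, rng):
        p = SimParams(s_plus=5.0, s_minus=-0.2, generations=50)
        sched = build_drought_schedule(50, 4, 4)
        res = run_replicate(p, sched, rng, record_trajectory=True)
        assert (res.trajectory["pop_size"] <= p.carrying_capacity).all()


class TestReplicates:
    def test_neutral_martingale(self):
        # allele frequency is a martingale without selection
        res = run_replicates(SimParams(), NO_DROUGHT, 10_000, seed=7)
        freqs = np.array([r.final_frequency for r in res])
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - 0.005) <= 3 * se

    def test_near_lethal_allele_is_lost_without_drought(self):
        res = run_replicates(
            SimParams(s_minus=-0.9), NO_DROUGHT, 1000, seed=11
        )
        assert np.mean([r.persisted for r in res]) <= 0.005

    def test_flags_consistent(self):
        res = run_replicates(
            SimParams(s_plus=5.0, generations=20),
            build_drought_schedule(20, 2, 4),
            500,
            seed=3,
        )
        for r in res:
            if r.fixed:
                assert r.persisted
            if r.extinct_population:
                assert not r.persisted and r.final_frequency == 0.0

    def test_seed_reproducibility(self):
        p = SimParams(s_plus=1.0, s_minus=-0.2)
        sched = build_drought_schedule(50, 2, 3)
        a = run_replicates(p, sched, 200, seed=99)
        b = run_replicates(p, sched, 200, seed=99)
        assert [r.final_frequency for r in a] == [r.final_frequency for r in b]


class TestGrid:
    def test_small_grid_deterministic_and_complete(self):
        kwargs = dict(
            s_plus_values=[1.0, 5.0],
            s_minus_values=[-0.1],
            n_events_values=[2],
            event_length_values=[3],
            replicates=100,
            seed=5,
        )
        a = run_grid(**kwargs)
        b = run_grid(**kwargs)
        assert a.equals(b)
        assert len(a) == 2
        assert set(a.columns) >= {
            "s_plus",
            "s_minus",
            "n_events",
            "event_length",
            "replicates",
            "persistence_prob",
            "mean_final_freq",
            "fixation_prob",
        }
        assert (a["fixation_prob"] <= a["persistence_prob"]).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_grid(replicates=0, seed=1)
        with pytest.raises(ValueError):
            run_grid(s_plus_values=[], seed=1)


class TestExactChain:
    def test_hand_enumerated_selfing_generation(self):
        # K=2, full selfing, neutral, one generation from (1 wt, 1 het):
        # parent picks are uniform, offspring i.i.d. with genotype
        # probabilities (5/8, 1/4, 1/8); multinomial over two offspring.
        p = SimParams(carrying_capacity=2, selfing_rate=1.0, generations=1)
        dist = exact_chain_distribution(p, NO_DROUGHT)
        expected = {
            (2, 0, 0): 25 / 64,
            (1, 1, 0): 20 / 64,
            (1, 0, 1): 10 / 64,
            (0, 2, 0): 4 / 64,
            (0, 1, 1): 4 / 64,
            (0, 0, 2): 1 / 64,
        }
        for state, prob in expected.items():
            assert dist[state] == pytest.approx(prob, abs=1e-12)

    def test_probability_mass_conserved(self):
        p = SimParams(
            carrying_capacity=3, selfing_rate=0.9, generations=10, s_minus=-0.5
        )
        dist = exact_chain_distribution(p, NO_DROUGHT)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_simulation_matches_chain_at_small_k(self):
        p = SimParams(carrying_capacity=2, selfing_rate=1.0, generations=5)
        dist = exact_chain_distribution(p, NO_DROUGHT)
        from collections import Counter

        n = 30_000
        counts = Counter()
        root = np.random.SeedSequence(17)
        for child in root.spawn(n):
            rng = np.random.Generator(np.random.PCG64(child))
            st_ = initialize_population(p)
            for g in range(1, p.generations + 1):
                if st_.pop_size == 0:
                    break
                st_ = next_generation(st_, NORMAL, p, rng)
            counts[(st_.n_wt_hom, st_.n_het, st_.n_te_hom)] += 1
        tv = 0.5 * sum(
            abs(dist.get(s, 0.0) - counts.get(s, 0) / n)
            for s in set(dist) | set(counts)
        )
        assert tv < 0.02

    def test_large_k_rejected(self):
        with pytest.raises(ValueError):
            exact_chain_distribution(SimParams(carrying_capacity=50), NO_DROUGHT)
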