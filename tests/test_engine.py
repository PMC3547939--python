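"""Generation loop invariants and the three experiments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichesim import (
    GenotypeSpace,
    ModelParams,
    PopulationState,
    Simulation,
    fitness,
    initial_state_appearance,
    recombine_sequential,
    run_appearance,
    run_completeness,
    run_mixing,
    step_generation,
    sweep,
)


class TestStepGeneration:
    def test_monomorphic_composition_constant_and_size_near_K(self):
        # r=0, single optimal genotype: composition cannot change and the
        # population fluctuates around carrying capacity
        p = ModelParams(L=3, s=0.1, fitness_model="additive", r=0.0, K=100_000)
        space = GenotypeSpace(3, 1)
        counts = np.zeros(space.size, dtype=np.int64)
        counts[0] = p.K
        sim = Simulation(p, PopulationState(0, counts), rng=np.random.default_rng(1), space=space)
        sizes = []
        for _ in range(300):
            sim.step()
            sizes.append(sim.state.N_total)
            assert (sim.state.counts[1:] == 0).all()
        assert np.mean(sizes) == pytest.approx(p.K, rel=0.02)

    def test_r_zero_present_genotype_set_never_grows(self, rng):
        p = ModelParams(L=4, s=0.05, fitness_model="additive", r=0.0, K=5000)
        space = GenotypeSpace(4, 1)
        for _ in range(5):
            counts = np.zeros(space.size, dtype=np.int64)
            idx = rng.choice(space.size, size=6, replace=False)
            counts[idx] = rng.integers(1, 1000, size=6)
            sim = Simulation(p, PopulationState(0, counts), rng=rng, space=space)
            present0 = set(np.flatnonzero(counts))
            for _ in range(50):
                sim.step()
            assert set(np.flatnonzero(sim.state.counts)) <= present0

    def test_counts_stay_integer_and_nonnegative(self, small_params, rng):
        space = GenotypeSpace(small_params.L, small_params.B)
        state = initial_state_appearance(small_params, space)
        for _ in range(30):
            state = step_generation(state, small_params, space, rng)
            assert state.counts.dtype.kind == "i"
            assert (state.counts >= 0).all()
            assert (state.niche_counts.sum(axis=0) == state.counts).all()

    def test_derived_genotype_reachable_only_by_recombination(self, rng):
        # clonal reproduction creates no new genotypes: with r=0 the all-1
        # genotype never arises from singles; a conversion event can make it
        p = ModelParams(L=2, s=0.01, fitness_model="additive", r=0.0, K=10_000)
        space = GenotypeSpace(2, 1)
        counts = np.zeros(space.size, dtype=np.int64)
        counts[0b00] = p.K - 2
        counts[0b01] = 1
        counts[0b10] = 1
        sim = Simulation(p, PopulationState(0, counts.copy()), rng=rng, space=space)
        for _ in range(100):
            sim.step()
            assert sim.state.counts[space.opt1].sum() == 0
        # ... whereas gene conversion between the two singles can assemble it
        pool = np.zeros(space.size, dtype=np.int64)
        pool[0b01] = 50
        pool[0b10] = 50
        made = any(
            recombine_sequential(pool, 30, space, np.random.default_rng(k))[0b11] > 0
            for k in range(20)
        )
        assert made

    def test_niche_label_symmetry_is_exact(self):
        # complementing every genotype and swapping niche labels maps the
        # model onto itself: fitness, preference, and loads are symmetric
        space = GenotypeSpace(L=5, B=1)
        p = ModelParams(L=5, s=0.07, fitness_model="additive")
        w = fitness(space, p)
        comp = (space.size - 1) ^ np.arange(space.size)  # complement all bits
        assert np.allclose(w[0], w[1][comp])
        assert np.allclose(space.f1, space.f0[comp])
        ws = fitness(space, ModelParams(L=5, s=0.07, fitness_model="step"))
        assert np.allclose(ws[0], ws[0][comp])

    def test_total_extinction_is_terminal(self, rng):
        p = ModelParams(L=2, s=0.01, fitness_model="additive", r=1e-3, K=100)
        space = GenotypeSpace(2, 1)
        counts = np.zeros(space.size, dtype=np.int64)
        sim = Simulation(p, PopulationState(0, counts), rng=rng, space=space)
        sim.step()
        assert sim.state.N_total == 0


class TestAppearanceExperiment:
    def test_r_zero_never_appears(self):
        p = ModelParams(L=3, s=0.1, fitness_model="additive", r=0.0, K=2000,
                        max_generations=400)
        for seed in range(3):
            out = run_appearance(p, seed=seed)
            assert not out.appeared
            assert out.extinct or out.censored

    def test_outcome_flags_mutually_exclusive(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=2000,
                        max_generations=300)
        for seed in range(6):
            out = run_appearance(p, seed=seed)
            assert sum([out.appeared, out.extinct, out.censored]) == 1
            if out.appeared:
                assert out.appearance_generation is not None

    def test_appearance_with_high_recombination_small_L(self):
        # two loci and plentiful recombination: the derived species is
        # assembled essentially always
        p = ModelParams(L=2, s=0.01, fitness_model="additive", r=1e-3, K=50_000,
                        max_generations=2000)
        outcomes = [run_appearance(p, seed=s) for s in range(5)]
        assert all(o.appeared for o in outcomes)

    def test_trajectory_recorded_when_requested(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=2000,
                        max_generations=100, trajectory_every=10)
        out = run_appearance(p, seed=0)
        assert out.trajectory is not None
        assert {"generation", "N_niche0", "N_niche1", "optimal_frequency"} <= set(out.trajectory.columns)


class TestCompletenessExperiment:
    def test_runs_full_span_and_reports_fraction(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=20_000,
                        max_generations=600, burn_in_generations=200)
        out = run_completeness(p, seed=1)
        assert out.generations_run == 600
        assert 0.0 <= out.completeness <= 1.0

    def test_low_recombination_speciation_near_complete(self):
        # with r tiny the optimal genotypes dominate both niches after burn-in
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-7, K=50_000,
                        max_generations=1500, burn_in_generations=500)
        out = run_completeness(p, seed=3)
        assert out.completeness > 0.9

    def test_neutral_control_stays_in_unit_interval(self):
        p = ModelParams(L=2, s=0.0, fitness_model="additive", r=1e-3, K=5000,
                        max_generations=400, burn_in_generations=100)
        out = run_completeness(p, seed=5)
        assert 0.0 <= out.completeness <= 1.0

    def test_completeness_nonincreasing_in_r_scaled_down(self):
        # qualitative tradeoff at reduced scale (short horizon, small K):
        # more recombination maintains more intermediates
        vals = []
        for r in (1e-6, 1e-4, 1e-2):
            p = ModelParams(L=3, s=0.01, fitness_model="additive", r=r, K=100_000,
                            max_generations=8000, burn_in_generations=4000)
            reps = [run_completeness(p, seed=11 + k).completeness for k in range(2)]
            vals.append(np.mean(reps))
        assert vals[0] >= vals[1] >= vals[2]


class TestMixingExperiment:
    def test_high_recombination_mixes_fast(self):
        p = ModelParams(L=3, s=0.01, fitness_model="additive", r=1e-2, K=50_000,
                        max_generations=5000)
        out = run_mixing(p, seed=2)
        assert out.t_mix is not None and out.t_mix < 1000

    def test_censoring_when_recombination_absent(self):
        p = ModelParams(L=3, s=0.01, fitness_model="additive", r=0.0, K=5000,
                        max_generations=200)
        out = run_mixing(p, seed=2)
        assert out.censored and out.t_mix is None

    def test_mean_t_mix_nonincreasing_in_r(self):
        # the central hitchhiking claim: more recombination, faster decay of
        # the background-niche association (10 replicates per rate)
        means = []
        for r in (1e-4, 1e-3, 1e-2):
            p = ModelParams(L=5, s=0.01, fitness_model="additive", r=r)
            t = [run_mixing(p, seed=100 + k).t_mix for k in range(10)]
            assert all(v is not None for v in t)
            means.append(np.mean(t))
        assert means[0] > means[1] > means[2]


class TestSweep:
    def test_single_cell_single_replicate(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=2000,
                        max_generations=100)
        res = sweep([(2, 1e-4)], p, 1, "appearance", master_seed=9)
        assert len(res.replicates) == 1
        assert res.summary.loc[0, "n_replicates"] == 1
        assert res.summary.loc[0, "p_appearance"] in (0.0, 1.0)

    def test_p_is_fraction_of_appeared(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-3, K=5000,
                        max_generations=400)
        res = sweep([(2, 1e-3)], p, 8, "appearance", master_seed=5)
        frac = res.replicates["appeared"].mean()
        assert res.summary.loc[0, "p_appearance"] == pytest.approx(frac)

    def test_reruns_bit_identical(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=3000,
                        max_generations=150)
        grid = [(2, 1e-4), (3, 1e-3)]
        a = sweep(grid, p, 3, "appearance", master_seed=77)
        b = sweep(grid, p, 3, "appearance", master_seed=77)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_matrix_layout_L_rows_r_columns(self):
        p = ModelParams(L=2, s=0.1, fitness_model="additive", r=1e-4, K=2000,
                        max_generations=100)
        res = sweep([(2, 1e-4), (2, 1e-3), (3, 1e-4), (3, 1e-3)], p, 2,
                    "appearance", master_seed=3)
        m = res.matrix("p_appearance")
        assert list(m.index) == [2, 3]
        assert list(m.columns) == [1e-4, 1e-3]
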