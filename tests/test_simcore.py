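"""Forward Wright-Fisher simulator: drift, mutation, conditioning, sampling."""

import numpy as np
import pytest

from sweepvolcano.simcore import (
    ConditioningError,
    PopulationState,
    SimParams,
    advance_generation,
    run_burn_in,
    run_conditioned_sweep,
    run_introgression_phase,
    sample_at_timepoints,
    scaled_time,
    take_sample,
    _make_rng,
    _step_inplace,
)


def small_params(**kw):
    defaults = dict(n_diploids=30, chrom_len=2000, mu=1e-5, rec=1e-6, sel_coeff=0.5, seed=1)
    defaults.update(kw)
    return SimParams(**defaults)


def empty_state(params):
    return PopulationState(
        params.n_diploids, params.chrom_len, _make_rng([params.seed, 99])
    )


class TestParams:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SimParams(n_diploids=1)
        with pytest.raises(ValueError):
            SimParams(mig_rate=1.5)
        with pytest.raises(ValueError):
            SimParams(dominance=2.0)

    def test_scaled_compound_parameters(self):
        p = SimParams()  # full-scale defaults
        assert p.theta_per_site == pytest.approx(0.0024)
        assert p.expected_mutations_per_generation == pytest.approx(900.0)
        assert p.effective_migration_rate == pytest.approx(0.2)

    def test_desk_scale_preserves_theta(self):
        p = SimParams.desk_scale()
        assert p.theta_per_site == pytest.approx(0.0024)
        assert p.rec * p.chrom_len == pytest.approx(0.3)


class TestBurnIn:
    def test_no_mutation_means_no_polymorphism(self):
        p = small_params(mu=0.0, burn_in_gens=50)
        state = run_burn_in(p)
        assert state.n_segregating == 0
        assert state.generation == 50

    def test_reproducible_from_seed(self):
        p = small_params(burn_in_gens=40)
        a, b = run_burn_in(p), run_burn_in(p)
        assert np.array_equal(a.positions, b.positions)
        assert all(np.array_equal(a.genos[k], b.genos[k]) for k in a.genos)

    def test_nonpositive_burn_in_rejected(self):
        with pytest.raises(ValueError):
            run_burn_in(small_params(burn_in_gens=0))


class TestGenerationStep:
    def test_advance_leaves_input_untouched_and_is_deterministic(self):
        p = small_params(burn_in_gens=30)
        state = run_burn_in(p)
        before = state.positions.copy()
        a = advance_generation(state, p)
        b = advance_generation(state, p)
        assert np.array_equal(state.positions, before)
        assert np.array_equal(a.positions, b.positions)
        assert a.generation == state.generation + 1

    def test_neutral_wf_sampling_is_binomial(self):
        # mu=rec=0, one allele at count k: offspring count matches the seeded
        # binomial draw and is a martingale in expectation
        p = small_params(mu=0.0, rec=0.0, sel_coeff=0.0)
        means = []
        k = 20
        for seed in range(200):
            st = empty_state(small_params(mu=0.0, seed=seed))
            st.positions = np.array([100], dtype=np.int64)
            st.genos["p1"] = np.zeros((60, 1), dtype=np.uint8)
            st.genos["p1"][:k, 0] = 1
            _step_inplace(st, p, selection_on=False, migration_on=False)
            count = k if st.n_segregating == 0 and st.fixed_positions.size else 0
            if st.n_segregating:
                count = int(st.genos["p1"][:, 0].sum())
            elif st.fixed_positions.size:
                count = 60
            means.append(count / 60)
        # martingale: E[p'] = p = 1/3; binomial SE over 200 reps
        se = np.sqrt((1 / 3) * (2 / 3) / 60 / 200)
        assert abs(np.mean(means) - 1 / 3) < 4 * se

    def test_full_migration_swaps_populations(self):
        p = small_params(mu=0.0, rec=0.0, sel_coeff=0.0, mig_rate=1.0)
        st = empty_state(p)
        st.positions = np.array([100], dtype=np.int64)
        st.genos["p1"] = np.ones((60, 1), dtype=np.uint8)
        st.genos["p2"] = np.zeros((60, 1), dtype=np.uint8)
        _step_inplace(st, p, selection_on=False, migration_on=True)
        # with m=1 every individual is a migrant: p1 becomes all-ancestral,
        # p2 all-derived (reproduction cannot mix, the pools are monomorphic)
        assert st.beneficial_pos is None
        assert st.genos["p1"].sum() == 0
        assert st.genos["p2"].sum() == st.genos["p2"].size

    def test_mutation_influx_matches_2NmuL(self):
        # fresh population: segregating sites after one generation = new
        # mutations; mean over replicates within 4 SE of 2N*mu*L = 30
        lam = 30.0
        p = small_params(n_diploids=50, chrom_len=10_000, mu=lam / (2 * 50 * 10_000), rec=0.0)
        counts = []
        for seed in range(150):
            st = empty_state(small_params(n_diploids=50, chrom_len=10_000, seed=seed))
            _step_inplace(st, p, selection_on=False, migration_on=False)
            counts.append(st.n_segregating)
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 4 * se


class TestConditionedSweep:
    def test_ends_fixed_and_starts_at_single_copy(self):
        p = small_params(burn_in_gens=30)
        state, traj = run_conditioned_sweep(run_burn_in(p), p)
        assert state.beneficial_freq("p1") == 1.0
        assert traj.freq_p1[0] == pytest.approx(1 / (2 * p.n_diploids))
        assert traj.fixation_gen_p1 == traj.generations[-1]

    def test_reproducible_trajectory(self):
        p = small_params(burn_in_gens=30, seed=7)
        base = run_burn_in(p)
        _, t1 = run_conditioned_sweep(base, p)
        _, t2 = run_conditioned_sweep(base, p)
        assert t1.freq_p1 == t2.freq_p1
        assert t1.n_restarts == t2.n_restarts

    def test_restart_cap_raises(self):
        p = small_params(mu=0.0, sel_coeff=0.0, burn_in_gens=5)
        with pytest.raises(ConditioningError):
            run_conditioned_sweep(run_burn_in(p), p, max_restarts=0, max_gens=5)

    def test_fixation_fraction_matches_markov_chain_oracle(self):
        # exact absorbing-chain fixation probability for the WF model with
        # fitnesses 1 / 1+hs / 1+s, starting from one copy
        N, s, h = 60, 0.5, 0.5
        n2 = 2 * N
        j = np.arange(n2 + 1)
        P = np.zeros((n2 + 1, n2 + 1))
        from scipy.stats import binom as sbinom

        for k in range(n2 + 1):
            pfreq = k / n2
            w_bar_num = pfreq**2 * (1 + s) + pfreq * (1 - pfreq) * (1 + h * s)
            w_bar = (
                pfreq**2 * (1 + s)
                + 2 * pfreq * (1 - pfreq) * (1 + h * s)
                + (1 - pfreq) ** 2
            )
            pstar = w_bar_num / w_bar if w_bar > 0 else 0.0
            P[k] = sbinom.pmf(j, n2, pstar)
        # absorbing probabilities u(k) solve u = P u with u(0)=0, u(2N)=1
        A = np.eye(n2 - 1) - P[1:-1, 1:-1]
        b = P[1:-1, -1]
        u = np.linalg.solve(A, b)
        p_fix = u[0]

        p = SimParams(n_diploids=N, chrom_len=1000, mu=0.0, rec=0.0, sel_coeff=s, seed=5)
        fixed = 0
        attempts = 400
        for i in range(attempts):
            st = PopulationState(N, 1000, _make_rng([i, 3]))
            st.introduce_beneficial("p1")
            while True:
                _step_inplace(st, p, selection_on=True, migration_on=False)
                f = st.beneficial_freq("p1")
                if f == 0.0 or f == 1.0:
                    fixed += f == 1.0
                    break
        se = np.sqrt(p_fix * (1 - p_fix) / attempts)
        assert abs(fixed / attempts - p_fix) < 3.5 * se


class TestIntrogression:
    def test_no_migration_means_no_introgression(self):
        p = small_params(
            n_diploids=20, burn_in_gens=20, mig_rate=0.0,
            pre_migration_gens=10, migration_phase_gens=30,
        )
        state = run_burn_in(p)
        state.add_population_copy("p2")
        state, traj = run_conditioned_sweep(state, p)
        snaps, traj2 = run_introgression_phase(state, p, [0.01], max_extra_gens=0)
        assert snaps == []
        assert traj2.fixation_gen_p2 is None
        assert all(f == 0.0 for f in traj2.freq_p2)

    def test_introgressed_allele_fixes_with_strong_migration(self):
        p = small_params(
            n_diploids=20, burn_in_gens=20, mig_rate=0.02,
            pre_migration_gens=10, migration_phase_gens=400,
        )
        state = run_burn_in(p)
        state.add_population_copy("p2")
        state, _ = run_conditioned_sweep(state, p)
        snaps, traj = run_introgression_phase(state, p, [0.01, 0.05], n_sequences=10)
        assert traj.fixation_gen_p2 is not None
        assert len(snaps) == 2
        assert snaps[0].population_label == "p2"
        assert snaps[0].time_scaled >= 0.01


class TestSampling:
    def test_complete_sample_contains_every_segregating_site(self):
        p = small_params(burn_in_gens=40)
        state = run_burn_in(p)
        m = take_sample(state, "p1", 2 * p.n_diploids, seed=1)
        seg = set(state.positions.tolist())
        assert seg <= set(m.positions.tolist())

    def test_subsample_of_high_frequency_site(self):
        # one site at count 2N-1: a subsample of 10 sees 9 or 10 copies;
        # when 10, the site is flagged as a substitution
        p = small_params(mu=0.0)
        seen = set()
        for seed in range(40):
            st = empty_state(p)
            st.positions = np.array([50], dtype=np.int64)
            st.genos["p1"] = np.ones((60, 1), dtype=np.uint8)
            st.genos["p1"][0, 0] = 0
            m = take_sample(st, "p1", 10, seed=seed)
            count = int(m.states.sum()) if m.n_sites else 0
            seen.add(count)
            if count == 10:
                assert bool(m.substitution[0])
            elif count == 9:
                assert not bool(m.substitution[0])
        assert seen <= {9, 10}
        assert seen == {9, 10}  # both outcomes occur across 40 seeds

    def test_sampling_too_many_sequences_errors(self):
        p = small_params()
        st = empty_state(p)
        with pytest.raises(ValueError):
            take_sample(st, "p1", 2 * p.n_diploids + 1, seed=0)

    def test_fixed_seed_reproducible(self):
        p = small_params(burn_in_gens=30)
        state = run_burn_in(p)
        a = take_sample(state, "p1", 10, seed=9)
        b = take_sample(state, "p1", 10, seed=9)
        assert np.array_equal(a.states, b.states)


class TestScaledTime:
    def test_basic_conversions(self):
        assert scaled_time(4000, 1000, 0) == pytest.approx(1.0)
        assert scaled_time(400, 1000, 0) == pytest.approx(0.1)
        assert scaled_time(500, 50, 100) == pytest.approx(2.0)

    def test_detection_horizon_consistency(self):
        # tau=0.4 at Ne=2e6 and 0.25 yr generations is 0.8 Myr
        tau, N, g = 0.4, 2e6, 0.25
        assert tau * 4 * N * g == pytest.approx(0.8e6)

    def test_invalid_population_size(self):
        with pytest.raises(ValueError):
            scaled_time(10, 0, 0)
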