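"""Simulator validation: closed-form neutral expectations, an independent
coalescent simulator (msprime) as distributional oracle, sweep endpoint
contracts, and the hitchhiking diversity trough."""

import math

import numpy as np
import pytest
from scipy import stats

import sweeppower as sp
from sweeppower.sumstats import pi, pi_in_window, tajimas_d


def harmonic(m):
    return sum(1.0 / i for i in range(1, m + 1))


class TestTrajectory:
    def test_endpoints_conditioned_on_fixation(self, nebraska):
        model, _ = nebraska
        sweep = sp.SweepModel(s=0.01, tau=0.1, x_sel=90_000)
        traj = sp.simulate_trajectory(model, sweep, seed=5)
        two_nb = traj.n_chromosomes
        assert two_nb == round(2 * model.f * model.N_anc)
        assert traj.freqs[0] == 1.0
        assert traj.freqs[-1] == pytest.approx(1.0 / two_nb)
        assert traj.freqs.min() >= 0 and traj.freqs.max() <= 1
        assert traj.fixation_time == sweep.tau
        assert traj.origin_time > sweep.tau

    def test_deterministic_logistic_sojourn_time(self):
        # fixation duration ~ (2/s) ln(2N - 1) for the logistic path
        model = sp.equilibrium_model(10_000)
        sweep = sp.SweepModel(s=0.01, tau=0.1, x_sel=0)
        traj = sp.simulate_trajectory(model, sweep, seed=0, mode="deterministic")
        expected = (2 / 0.01) * math.log(2 * 10_000 - 1)
        assert traj.duration_generations == pytest.approx(expected, rel=0.01)

    def test_auto_mode_switches_on_drift_strength(self, florida, nebraska):
        fl_model, _ = florida
        swp = sp.SweepModel(s=0.01, tau=0.1, x_sel=0)
        assert sp.simulate_trajectory(fl_model, swp, seed=1).mode == "stochastic"
        big = sp.equilibrium_model(1e6)
        assert sp.simulate_trajectory(big, swp, seed=1).mode == "deterministic"

    def test_sweep_durations_stay_within_the_studied_band(self, nebraska):
        # all selection strengths fix well within 0.3 x 2N generations
        model, _ = nebraska
        for s in (0.001, 0.01, 0.1):
            traj = sp.simulate_trajectory(
                model, sp.SweepModel(s=s, tau=0.1, x_sel=0), seed=11)
            dur_2N = traj.origin_time - traj.fixation_time
            assert 0 < dur_2N < 0.3

    def test_sweep_overflowing_the_epoch_is_an_error(self):
        model = sp.DemographicModel(N_anc=5000, f=0.01, c_recovery=1, d=0.11,
                                    t_r=0.01)
        sweep = sp.SweepModel(s=0.001, tau=0.1, x_sel=0)
        with pytest.raises(ValueError, match="raise s or shorten tau"):
            for seed in range(20):  # drift makes the duration stochastic
                sp.simulate_trajectory(model, sweep, seed=seed)


class TestNeutralExpectations:
    def test_pairwise_diversity_matches_4Nmu(self):
        # E[pi] = theta for n=2 at equilibrium
        model = sp.equilibrium_model(1000)
        region = sp.RegionConfig(L=10_000, n=2, mu=1e-7, r=1e-7)
        vals = [pi(sp.simulate_neutral_sample(model, region, s))
                for s in range(1500)]
        theta = 4 * 1000 * 1e-7
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - theta) < 3 * se

    def test_segregating_sites_match_watterson(self):
        # E[S] = theta_region * a_{n-1} with the Florida-scale theta
        model = sp.equilibrium_model(2482)
        region = sp.RegionConfig(L=180_000, n=40, mu=3.7e-8, r=5.6e-7)
        S = [sp.simulate_neutral_sample(model, region, s).S for s in range(250)]
        expected = 4 * 2482 * 3.7e-8 * 180_000 * harmonic(39)
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - expected) < 3 * se

    def test_bottleneck_skews_spectrum_negative(self, florida_neutral_reps):
        d_vals = [tajimas_d(h) for h in florida_neutral_reps if h.S > 0]
        assert np.mean(d_vals) < 0


class TestAgainstIndependentSimulator:
    """Two-sample KS comparisons against msprime under matched parameters."""

    def _msprime_reps(self, model, region, n_reps, seed0):
        import msprime

        out = []
        for seed in range(seed0, seed0 + n_reps):
            dem = msprime.Demography()
            dem.add_population(initial_size=model.N_contemporary)
            dem.add_population_parameters_change(
                time=model.to_generations(model.t_r),
                initial_size=model.N_bottleneck)
            dem.add_population_parameters_change(
                time=model.to_generations(model.d), initial_size=model.N_anc)
            ts = msprime.sim_ancestry(
                samples=region.n // 2, demography=dem,
                sequence_length=region.L, recombination_rate=region.r,
                random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=region.mu, random_seed=seed + 1,
                                       discrete_genome=False)
            out.append((ts.num_sites, float(ts.diversity(mode="site"))))
        return out

    def test_neutral_bottleneck_distribution_matches(self, florida):
        model, _ = florida
        region = sp.RegionConfig(L=60_000, n=40, mu=3.7e-8, r=5.6e-7)
        ours = [sp.simulate_neutral_sample(model, region, s) for s in range(250)]
        oracle = self._msprime_reps(model, region, 250, seed0=1)
        ks_S = stats.ks_2samp([h.S for h in ours], [s for s, _ in oracle])
        ks_pi = stats.ks_2samp([pi(h) for h in ours], [p for _, p in oracle])
        assert ks_S.pvalue > 0.01
        assert ks_pi.pvalue > 0.01

    def test_weak_sweep_degenerates_to_neutral(self, florida):
        model, _ = florida
        region = sp.RegionConfig(L=60_000, n=40, mu=3.7e-8, r=5.6e-7)
        sweep = sp.SweepModel(s=1e-4, tau=0.1, x_sel=30_000)
        swept = [sp.simulate_sweep_sample(model, sweep, region, s).S
                 for s in range(250)]
        neutral = [sp.simulate_neutral_sample(model, region, 5000 + s).S
                   for s in range(250)]
        assert stats.ks_2samp(swept, neutral).pvalue > 0.01


class TestSweepFootprint:
    def test_hitchhiking_carves_a_diversity_trough(self):
        # strong recent sweep: near-site pi < 10% of the neutral mean
        model = sp.equilibrium_model(5000)
        region = sp.RegionConfig(L=50_000, n=20, mu=3.7e-8, r=5.6e-7)
        sweep = sp.SweepModel(s=0.5, tau=0.01, x_sel=25_000)
        near = [pi_in_window(sp.simulate_sweep_sample(model, sweep, region, s),
                             25_000, 500)
                for s in range(60)]
        neutral = [pi(sp.simulate_neutral_sample(model, region, 900 + s))
                   for s in range(60)]
        assert np.mean(near) < 0.1 * np.mean(neutral)


class TestMatrixContracts:
    @pytest.mark.parametrize("kind", ["neutral", "sweep"])
    @pytest.mark.parametrize("seed", range(4))
    def test_output_matrices_satisfy_their_invariants(self, kind, seed, florida):
        model, _ = florida
        region = sp.RegionConfig(L=40_000, n=17, mu=1e-7, r=5.6e-7)
        if kind == "neutral":
            h = sp.simulate_neutral_sample(model, region, seed)
        else:
            h = sp.simulate_sweep_sample(
                model, sp.SweepModel(s=0.05, tau=0.1, x_sel=20_000), region, seed)
        h.validate()
        assert np.all(np.diff(h.positions) > 0)
        assert h.positions.min() >= 0 and h.positions.max() < region.L
        counts = h.derived_counts()
        if h.S:
            assert counts.min() >= 1 and counts.max() <= region.n - 1
        assert h.metadata["kind"] == kind

    def test_fixed_seed_is_reproducible(self, florida):
        model, region = florida
        a = sp.simulate_neutral_sample(model, region, 123)
        b = sp.simulate_neutral_sample(model, region, 123)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_replicate_seed_scheme_is_stable(self):
        seeds = sp.replicate_seeds(7, 3)
        assert [s.spawn_key for s in seeds] == [(0,), (1,), (2,)]
        assert all(s.entropy == 7 for s in seeds)
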