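"""CLR scan: projection arithmetic, the escape-lineage mixture against an
independent enumeration oracle, and the scan's nesting/localization
properties."""

import math

import numpy as np
import pytest

import sweeppower as sp
from sweeppower.sfscan import _ClrTables, default_alpha_grid, grid_positions
from sweeppower.sumstats import SiteFrequencySpectrum


def spectrum(counts, n):
    return SiteFrequencySpectrum(np.asarray(counts, dtype=float), n)


def oracle_site_probability(b_counts, n, d, alpha, k):
    """Exhaustive enumeration over escapee counts and ancestral configs."""
    b = np.asarray(b_counts, dtype=float)
    b = b / b.sum()
    p_e = 1.0 - math.exp(-alpha * d)
    mass = np.zeros(n + 1)
    for e in range(n + 1):
        w = math.comb(n, e) * p_e**e * (1 - p_e) ** (n - e)
        if e == n:
            mass[1:n] += w * b
            continue
        m = e + 1
        for j in range(1, n):  # background class of the ancestral site
            for jp in range(0, m + 1):  # derived among the m ancestors
                hyp = (math.comb(j, jp) * math.comb(n - j, m - jp)
                       / math.comb(n, m)) if jp <= j and m - jp <= n - j else 0.0
                if hyp == 0.0:
                    continue
                # swept ancestor is one of the m, uniformly
                mass[(n - e) + (jp - 1)] += w * b[j - 1] * hyp * (jp / m)
                mass[jp] += w * b[j - 1] * hyp * (1 - jp / m)
    poly = mass[1:n]
    return poly[k - 1] / poly.sum()


class TestBackgroundSpectrum:
    def test_single_region_is_its_own_spectrum(self, florida_neutral_reps):
        h = florida_neutral_reps[0]
        b = sp.background_spectrum(h)
        raw = sp.sfs(h)
        np.testing.assert_allclose(b.counts, raw.counts / raw.total)

    def test_pooling_identical_region_is_idempotent(self, florida_neutral_reps):
        h = florida_neutral_reps[0]
        np.testing.assert_allclose(
            sp.background_spectrum(h, [h]).counts,
            sp.background_spectrum(h).counts)

    def test_pooled_counts_add(self):
        # focal 2 singletons + extra 2 doubletons -> (0.5, 0.5, 0)
        a = np.zeros((4, 2), dtype=np.uint8)
        a[0, 0] = a[1, 1] = 1
        focal = sp.HaplotypeMatrix(a, np.array([1.0, 2.0]), 10.0)
        e = np.zeros((4, 2), dtype=np.uint8)
        e[:2, 0] = 1
        e[2:, 1] = 1
        extra = sp.HaplotypeMatrix(e, np.array([1.0, 2.0]), 10.0)
        b = sp.background_spectrum(focal, [extra])
        np.testing.assert_allclose(b.counts, [0.5, 0.5, 0.0])

    def test_empty_pool_is_an_error(self):
        h = sp.HaplotypeMatrix(np.zeros((4, 0), dtype=np.uint8), np.zeros(0), 10.0)
        with pytest.raises(ValueError, match="empty"):
            sp.background_spectrum(h)


class TestDownsample:
    def test_identity_at_full_size(self):
        b = spectrum([3, 2, 1], 4).normalize()
        q = sp.downsample_spectrum(b, 4)
        np.testing.assert_allclose(q[1:4], b.counts)
        assert q[0] == 0 and q[4] == 0

    def test_singletons_to_pairs(self):
        # n=4 all singletons projected to m=2: P(1)=C(1,1)C(3,1)/C(4,2)=0.5
        b = spectrum([4, 0, 0], 4)
        np.testing.assert_allclose(sp.downsample_spectrum(b, 2), [0.5, 0.5, 0.0])

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_projected_mass_is_conserved(self, m):
        b = spectrum([5, 1, 2, 7], 5)
        assert sp.downsample_spectrum(b, m).sum() == pytest.approx(1.0)

    def test_oversampling_is_an_error(self):
        with pytest.raises(ValueError):
            sp.downsample_spectrum(spectrum([1, 1, 1], 4), 5)


class TestSweepSiteProbability:
    @pytest.mark.parametrize("n,counts", [(4, [5, 3, 2]), (6, [8, 4, 2, 1, 1])])
    def test_probabilities_sum_to_one(self, n, counts):
        b = spectrum(counts, n)
        for alpha, d in [(1e-4, 100), (1e-3, 5000), (0.0, 1000), (1.0, 2)]:
            total = sum(
                sp.sweep_site_probability(b, d, alpha, k, n) for k in range(1, n)
            )
            assert total == pytest.approx(1.0)

    @pytest.mark.parametrize("n,counts", [(4, [5, 3, 2]), (6, [8, 4, 2, 1, 1])])
    @pytest.mark.parametrize("alpha_d", [0.01, 0.5, 3.0])
    def test_matches_exhaustive_enumeration(self, n, counts, alpha_d):
        b = spectrum(counts, n)
        for k in range(1, n):
            got = sp.sweep_site_probability(b, 1000.0, alpha_d / 1000.0, k, n)
            want = oracle_site_probability(counts, n, 1000.0, alpha_d / 1000.0, k)
            assert got == pytest.approx(want, rel=1e-10)

    def test_strong_escape_recovers_background(self):
        b = spectrum([5, 3, 2], 4).normalize()
        for k in (1, 2, 3):
            assert sp.sweep_site_probability(b, 50.0, 1.0, k, 4) == pytest.approx(
                b.counts[k - 1], abs=1e-10)

    def test_full_collapse_concentrates_at_the_extremes(self):
        # alpha = 0: conditioning leaves only the single-escapee classes
        b = spectrum([5, 3, 2], 4)
        p = [sp.sweep_site_probability(b, 1000.0, 0.0, k, 4) for k in (1, 2, 3)]
        assert p[0] + p[2] == pytest.approx(1.0)
        assert p[1] == pytest.approx(0.0)

    def test_invalid_count_rejected(self):
        b = spectrum([1, 1, 1], 4)
        with pytest.raises(ValueError):
            sp.sweep_site_probability(b, 10.0, 0.1, 0, 4)
        with pytest.raises(ValueError):
            sp.sweep_site_probability(b, 10.0, 0.1, 4, 4)


class TestClrScan:
    def test_lattice_interpolation_is_accurate(self):
        b = spectrum([30, 12, 5, 2, 1], 6).normalize()
        tables = _ClrTables(b)
        rng = np.random.default_rng(0)
        ad = rng.uniform(1e-6, 40, size=50)
        k_idx = rng.integers(0, 5, size=50)
        exact = np.array([
            math.log(sp.sweep_site_probability(b, a, 1.0, k + 1, 6))
            for a, k in zip(ad, k_idx)
        ])
        np.testing.assert_allclose(tables.site_loglik(ad, k_idx), exact, atol=5e-3)

    def test_lambda_nonnegative_and_zero_on_flat_spectrum(self):
        # every site at the same derived count: the background is a point
        # mass, no sweep intensity can beat it, Lambda == 0 everywhere
        n, S = 8, 20
        alleles = np.zeros((n, S), dtype=np.uint8)
        alleles[:3, :] = 1
        h = sp.HaplotypeMatrix(alleles, np.linspace(10, 990, S), 1000.0)
        res = sp.clr_scan(h, study=sp.StudyConfig(grid_spacing_bp=100))
        assert res.statistic.min() >= -1e-9
        assert res.max_value <= 1e-9

    def test_lambda_nonnegative_on_simulated_data(self, florida_neutral_reps):
        for h in florida_neutral_reps[:5]:
            res = sp.clr_scan(h)
            assert res.statistic.min() >= -1e-9

    def test_profile_translation_invariance(self, florida_neutral_reps):
        h = florida_neutral_reps[0]
        study = sp.StudyConfig(grid_spacing_bp=1000)
        ag = default_alpha_grid(h.L)
        base = sp.clr_scan(h, study=study, alpha_grid=ag)
        shift = 3000.0
        moved = sp.HaplotypeMatrix(
            h.alleles, h.positions + shift, h.L + shift)
        res = sp.clr_scan(moved, study=study, alpha_grid=ag)
        k = int(shift / 1000)
        np.testing.assert_allclose(
            res.statistic[k:len(base.statistic) + k], base.statistic,
            atol=1e-6)

    def test_localizes_a_strong_recent_sweep(self):
        model = sp.equilibrium_model(10_000)
        region = sp.RegionConfig(L=90_000, n=30, mu=3.7e-8, r=5.6e-7)
        sweep = sp.SweepModel(s=0.1, tau=0.01, x_sel=45_000)
        hits = 0
        for seed in range(12):
            h = sp.simulate_sweep_sample(model, sweep, region, seed)
            res = sp.clr_scan(h)
            hits += abs(res.max_position - 45_000) <= 10_000
        assert hits >= 7  # majority of replicates

    def test_recent_fixations_easier_than_old_ones(self):
        # matched seeds; localization within 10 kb as the power proxy.  A
        # milder bottleneck and strong selection give the scan something to
        # find at tau=0.01; by tau=0.3 the bottleneck has erased it.
        model = sp.DemographicModel(N_anc=50_000, f=0.05, c_recovery=1.0,
                                    d=0.5, t_r=0.01)
        region = sp.RegionConfig()
        hits = {}
        for tau in (0.01, 0.3):
            sweep = sp.SweepModel(s=0.1, tau=tau, x_sel=90_000)
            hits[tau] = sum(
                abs(sp.clr_scan(
                    sp.simulate_sweep_sample(model, sweep, region, seed)
                ).max_position - 90_000) <= 10_000
                for seed in range(15)
            )
        assert hits[0.01] >= hits[0.3]

    def test_alpha_grid_contains_the_null(self):
        grid = default_alpha_grid(180_000)
        assert np.isinf(grid[-1])
        assert len(grid) == 41

    def test_grid_positions_cover_region(self):
        g = grid_positions(180_000, 1000)
        assert len(g) == 181
        assert g[0] == 0 and g[-1] == 180_000
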