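import math

import numpy as np
import pytest

from parapop.coalsim import (DemographyModel, Epoch, SimConfig, masked_rerun,
                             mutate_fixed_s, mutate_theta,
                             rejection_probability, rejection_report,
                             simulate_genealogy, simulate_replicates)
from parapop.diversity import watterson_a1


NE = 10_000.0


class TestDemographyModel:
    def test_epochs_must_be_contiguous(self):
        with pytest.raises(ValueError):
            DemographyModel([Epoch(0, 100, 500), Epoch(150, math.inf, 500)])

    def test_european_default_epoch_boundaries(self):
        dem = DemographyModel.european_default()
        assert [e.start_gen for e in dem.epochs] == [0.0, 840.0, 2040.0]
        assert dem.epochs[1].ne_start == 1861.0
        # exponential epoch interpolates from present size down to the bottleneck
        assert dem.epochs[0].ne_at(0.0) == pytest.approx(10_000.0)
        assert dem.epochs[0].ne_at(840.0) == pytest.approx(1861.0, rel=1e-9)

    def test_text_round_trip(self):
        dem = DemographyModel.european_default()
        back = DemographyModel.from_text(dem.to_text())
        assert [(e.start_gen, e.end_gen, e.ne_start, e.growth)
                for e in back.epochs] == [(e.start_gen, e.end_gen, e.ne_start, e.growth)
                                          for e in dem.epochs]


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self, rng):
        dem = DemographyModel.constant(NE)
        ts = [simulate_genealogy(2, dem, rng).tmrca() for _ in range(3000)]
        se = np.std(ts) / np.sqrt(len(ts))
        assert abs(np.mean(ts) - 2 * NE) < 3 * se

    def test_total_branch_length_expectation(self, rng):
        dem = DemographyModel.constant(NE)
        tot = [simulate_genealogy(10, dem, rng).total_branch_length()
               for _ in range(3000)]
        expected = 4 * NE * watterson_a1(10)
        se = np.std(tot) / np.sqrt(len(tot))
        assert abs(np.mean(tot) - expected) < 3 * se


class TestMutation:
    def test_zero_mutations(self, rng):
        tree = simulate_genealogy(6, DemographyModel.constant(NE), rng)
        res = mutate_fixed_s(tree, 0, rng)
        assert res.sfs.S == 0 and res.k == 1

    def test_sfs_conservation(self, rng):
        dem = DemographyModel.constant(NE)
        for _ in range(20):
            tree = simulate_genealogy(12, dem, rng)
            S = int(rng.integers(1, 30))
            assert mutate_fixed_s(tree, S, rng).sfs.S == S

    def test_two_samples_all_singletons(self, rng):
        tree = simulate_genealogy(2, DemographyModel.constant(NE), rng)
        res = mutate_fixed_s(tree, 7, rng)
        assert res.sfs.xi.tolist() == [7.0]

    def test_theta_mode_segregating_sites_expectation(self, rng):
        """E[S] = theta * a1 for constant size."""
        dem = DemographyModel.constant(NE)
        theta = 5.0
        Ss = []
        for _ in range(2000):
            tree = simulate_genealogy(10, dem, rng)
            Ss.append(mutate_theta(tree, theta, NE, rng).sfs.S)
        expected = theta * watterson_a1(10)
        se = np.std(Ss) / np.sqrt(len(Ss))
        assert abs(np.mean(Ss) - expected) < 3 * se


class TestReplicates:
    def test_seed_determinism(self):
        cfg = SimConfig(n=10, replicates=50, seed=99, fixed_S=12)
        dem = DemographyModel.constant(NE)
        a = simulate_replicates(cfg, dem)
        b = simulate_replicates(cfg, dem)
        assert a.equals(b)

    def test_theta_mode_unbiased_summaries(self):
        """Unconditional neutral simulation reproduces E[theta_pi]=theta and
        mean H = 0 within Monte-Carlo error."""
        theta = 44 / watterson_a1(64)
        cfg = SimConfig(n=64, replicates=3000, seed=5, theta=theta)
        df = simulate_replicates(cfg, DemographyModel.constant(NE))
        se_pi = df.theta_pi.std() / np.sqrt(len(df))
        assert abs(df.theta_pi.mean() - theta) < 3 * se_pi
        se_h = df.H.std() / np.sqrt(len(df))
        assert abs(df.H.mean()) < 3 * se_h

    def test_recent_bottleneck_shifts_d_positive(self):
        """A partial recent bottleneck leaves few deep lineages (excess
        intermediate frequencies): mean D rises above the constant-size mean.
        The packaged bottleneck+expansion model shows the same shift."""
        neutral = DemographyModel.constant(NE)
        bottl = DemographyModel([Epoch(0, 300, NE / 100), Epoch(300, math.inf, NE)])
        cfg = lambda seed: SimConfig(n=30, replicates=800, seed=seed, fixed_S=30)
        d_neu = simulate_replicates(cfg(1), neutral).D.mean()
        d_bot = simulate_replicates(cfg(2), bottl).D.mean()
        assert d_bot > d_neu + 0.2
        cfg64 = lambda seed: SimConfig(n=64, replicates=800, seed=seed, fixed_S=44)
        d_eur = simulate_replicates(cfg64(3), DemographyModel.european_default()).D.mean()
        d_neu64 = simulate_replicates(cfg64(4), neutral).D.mean()
        assert d_eur > d_neu64 + 0.2

    def test_pure_growth_shifts_d_negative(self):
        """Exponential expansion (no bottleneck) skews spectra toward rare
        alleles: mean D falls below the constant-size mean."""
        neutral = DemographyModel.constant(NE)
        growth = DemographyModel([Epoch(0, 840, NE, math.log(NE / 100) / 840),
                                  Epoch(840, math.inf, 100.0)])
        cfg = lambda seed: SimConfig(n=30, replicates=800, seed=seed, fixed_S=30)
        d_neu = simulate_replicates(cfg(3), neutral).D.mean()
        d_gro = simulate_replicates(cfg(4), growth).D.mean()
        assert d_gro < d_neu - 0.2

    def test_two_epoch_sfs_matches_msprime_oracle(self):
        """Mean unfolded SFS under a two-epoch model agrees with msprime."""
        import msprime
        n = 12
        reps = 1500
        anc, rec, t_change = 10_000.0, 1_000.0, 1_000.0
        dem = DemographyModel([Epoch(0, t_change, rec), Epoch(t_change, math.inf, anc)])
        cfg = SimConfig(n=n, replicates=reps, seed=17, fixed_S=20)
        rng = np.random.default_rng(17)
        mine = np.zeros(n - 1)
        for _ in range(reps):
            tree = simulate_genealogy(n, dem, rng)
            mine += mutate_fixed_s(tree, 20, rng).sfs.xi
        mine /= reps

        ms_dem = msprime.Demography()
        ms_dem.add_population(initial_size=rec)
        ms_dem.add_population_parameters_change(time=t_change, initial_size=anc)
        other = np.zeros(n - 1)
        counts = []
        rng2 = np.random.default_rng(23)
        for ts in msprime.sim_ancestry(samples=n, ploidy=1, demography=ms_dem,
                                       num_replicates=reps, random_seed=11):
            # place 20 mutations proportional to branch length, like fixed-S
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            bl = np.array([tree.branch_length(u) for u in nodes])
            pick = rng2.choice(len(nodes), size=20, p=bl / bl.sum())
            for b in pick:
                c = tree.num_samples(nodes[b])
                other[c - 1] += 1
        other /= reps
        # agreement within Monte-Carlo error on every frequency class
        se = np.sqrt((mine * (1 + mine)) / reps) + np.sqrt((other * (1 + other)) / reps)
        assert np.all(np.abs(mine - other) < 4 * se + 0.05)


class TestRejection:
    def test_extreme_observation(self):
        vals = np.arange(1000, dtype=float)
        assert rejection_probability(-1.0, vals, "lower") == pytest.approx(1 / 1001)
        assert rejection_probability(2000.0, vals, "upper") == pytest.approx(1 / 1001)

    def test_median_observation(self):
        vals = np.arange(1001, dtype=float)
        assert rejection_probability(500.0, vals, "lower") == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_observed(self, rng):
        vals = rng.normal(size=500)
        ps = [rejection_probability(x, vals, "lower") for x in (-2, -1, 0, 1, 2)]
        assert ps == sorted(ps)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            rejection_probability(0.0, [1.0] * 50)


class TestMaskedRerun:
    def test_masking_tract_with_no_sites_is_identity(self, default_site_tables):
        sa, _ = default_site_tables
        masked = sa.drop_intervals([(2000, 2001)]) if not any(
            2000 <= p <= 2001 for p in sa.positions) else sa
        assert masked.S == sa.S

    def test_masked_s_feeds_null(self, default_dataset, default_site_tables):
        from parapop.popdata import collapse_haplotypes, polarize_sites, subset_columns
        ds = default_dataset
        sa, _ = default_site_tables
        pol = polarize_sites(sa, ds.outgroup)
        aln_m = subset_columns(ds.aln_a, [(624, 634), (3080, 3186)], "drop")
        hap_m = [c for _, c in collapse_haplotypes(aln_m)]
        cfg = SimConfig(n=64, replicates=150, seed=2, fixed_S=44)
        masked, report = masked_rerun(pol, hap_m, [(624, 634), (3080, 3186)],
                                      cfg, DemographyModel.european_default(),
                                      frame_length=3357)
        assert masked.S == 34
        assert report.S_used == 34
        assert set(report.p_values) <= {"D", "Fs", "H", "nH"}
        assert all(0 < p <= 1 for p in report.p_values.values())

    def test_tract_outside_frame_rejected(self, default_site_tables):
        sa, _ = default_site_tables
        with pytest.raises(ValueError):
            masked_rerun(sa, [1] * 33, [(5000, 5100)],
                         SimConfig(n=64, replicates=150, seed=1, fixed_S=44),
                         DemographyModel.european_default(), frame_length=3357)

    def test_masking_everything_flags_undefined(self):
        from parapop.popdata import SiteRecord, SiteTable
        empty = SiteTable([], 64)
        rep = rejection_report(empty, [64], SimConfig(n=64, replicates=150,
                                                      seed=1, fixed_S=1),
                               DemographyModel.constant(NE))
        assert rep.p_values == {} or all(np.isfinite(list(rep.p_values.values())))
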