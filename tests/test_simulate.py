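import numpy as np
import pytest
from scipy import stats

from mthaplo.simulate import (DemographicModel, MutationModel,
                              evolve_sequences, make_frequency_sites,
                              make_sister_haplogroup_dataset,
                              simulate_coalescent)
from mthaplo.variants import call_variants, synthetic_reference


class TestCoalescent:
    def test_two_tip_tmrca_matches_analytic_mean(self, constant_demography):
        """E[T2] = Ne generations = 25,000 years for haploid Ne=1000."""
        times = [simulate_coalescent(2, constant_demography, seed).root.time
                 for seed in range(2000)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 25000.0) < 3 * se

    def test_ten_tip_tmrca_matches_analytic_mean(self, constant_demography):
        """E[TMRCA(10)] = 2 Ne (1 - 1/10) generations."""
        expect = 2 * 1000 * (1 - 0.1) * 25.0
        times = [simulate_coalescent(10, constant_demography, s).root.time
                 for s in range(800)]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - expect) < 3 * se

    def test_huge_ancient_population_blocks_old_coalescence(self):
        """With Ne -> huge before 10 ka, almost no events are older."""
        # recent Ne=50 over 400 generations: P(no event) = exp(-8)
        dem = DemographicModel(((0.0, 50.0), (10000.0, 1e9)), 25.0)
        old = sum(simulate_coalescent(2, dem, s).root.time > 10000
                  for s in range(300))
        assert old <= 2

    def test_reproducible_and_ultrametric(self, constant_demography):
        a = simulate_coalescent(8, constant_demography, 123)
        b = simulate_coalescent(8, constant_demography, 123)
        ta = sorted(n.time for n in a.preorder())
        tb = sorted(n.time for n in b.preorder())
        assert ta == tb
        for node in a.preorder():
            if node.parent is not None:
                assert node.parent.time > node.time
        assert all(t.time == 0.0 for t in a.tips())

    def test_interval_distribution_is_exponential(self, constant_demography):
        """Rescaled coalescent intervals pool to Exp(1) (KS at alpha=0.01)."""
        draws = []
        for s in range(1000):
            g = simulate_coalescent(11, constant_demography, s)
            times = sorted(n.time / 25.0 for n in g.preorder()
                           if not n.is_tip)
            prev, k = 0.0, 11
            for t in times:
                draws.append((t - prev) * k * (k - 1) / 2.0 / 1000.0)
                prev, k = t, k - 1
        assert len(draws) == 10000
        _, p = stats.kstest(draws, "expon")
        assert p > 0.01


class TestSequenceEvolution:
    def test_zero_rate_keeps_tips_identical(self, toy_reference,
                                            constant_demography, hky_model):
        g = simulate_coalescent(5, constant_demography, 3)
        aln, _ = evolve_sequences(g, toy_reference, hky_model, 0.0, seed=1)
        assert set(aln.values()) == {toy_reference.bases}

    def test_total_mutation_count_is_poisson_mean(self, toy_reference,
                                                  constant_demography,
                                                  hky_model):
        """Total events over the tree match T x rate within 3 SE."""
        g = simulate_coalescent(6, constant_demography, 5)
        tree_years = sum(n.parent.time - n.time for n in g.preorder()
                         if n.parent is not None)
        clock = 1 / 500.0
        rate_total = clock * (hky_model.kappa + 2) / hky_model.kappa
        counts = []
        for s in range(300):
            _, mt = evolve_sequences(g, toy_reference, hky_model, clock,
                                     seed=s)
            counts.append(mt.total_mutations())
        expect = tree_years * rate_total
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_hotspot_accumulates_proportionally_more_hits(
            self, constant_demography):
        ref = synthetic_reference(50, seed=2)
        rates = [1.0] * 50
        rates[9] = 10.0
        mm = MutationModel(site_rates=tuple(rates))
        g = simulate_coalescent(4, constant_demography, 11)
        hot = base = 0
        for s in range(400):
            _, mt = evolve_sequences(g, ref, mm, 1 / 300.0, seed=s)
            for node in mt.preorder():
                for v in node.mutations:
                    if v.position == 10:
                        hot += 1
                    elif v.position == 20:
                        base += 1
        assert base > 30  # enough signal to compare
        assert 7.0 < hot / base < 13.0

    def test_true_branch_mutations_reproduce_tip_profiles(
            self, toy_reference, constant_demography, hky_model):
        g = simulate_coalescent(6, constant_demography, 9)
        aln, mt = evolve_sequences(g, toy_reference, hky_model, 1 / 200.0,
                                   seed=4)
        for tip in mt.tips():
            path = {(v.position, v.alt_base)
                    for v in mt.tip_profile(tip) if v.is_substitution}
            called = {(v.position, v.alt_base)
                      for v in call_variants(aln[tip.name],
                                             toy_reference).variants}
            assert path == called


class TestSisterDataset:
    def test_structure_and_truth(self, toy_reference, hky_model):
        dem = DemographicModel(((0.0, 400.0),), 25.0)
        ds = make_sister_haplogroup_dataset(
            46000.0, 6, dem, seed=8, reference=toy_reference,
            mut_model=hky_model)
        assert len(ds.true_tree.root.children) == 2
        assert len(ds.profiles) == 12
        for name, tmrca in ds.clade_tmrcas.items():
            assert tmrca < ds.split_time
            clade = ds.true_tree.find(name)
            tips = {t.name for t in ds.true_tree.clade_tips(clade)}
            assert tips == set(ds.clade_tips[name])

    def test_bit_reproducible(self, toy_reference, hky_model):
        dem = DemographicModel(((0.0, 400.0),), 25.0)
        a = make_sister_haplogroup_dataset(46000.0, 5, dem, seed=3,
                                           reference=toy_reference,
                                           mut_model=hky_model)
        b = make_sister_haplogroup_dataset(46000.0, 5, dem, seed=3,
                                           reference=toy_reference,
                                           mut_model=hky_model)
        assert a.alignment == b.alignment
        assert a.clade_tmrcas == b.clade_tmrcas


class TestFrequencySites:
    def test_zero_surface_gives_zero_counts(self):
        df = make_frequency_sites(10, lambda lon, lat: 0.0, seed=1)
        assert (df["U6"] == 0).all()

    def test_large_samples_concentrate_on_truth(self):
        df = make_frequency_sites(30, lambda lon, lat: 0.4, seed=2,
                                  n_samples=4000)
        freq = df["U6"] / df["n"]
        # 99.9% binomial band around 0.4 at n=4000
        assert ((freq - 0.4).abs() < 3.3 * np.sqrt(0.4 * 0.6 / 4000)).all()

    def test_logistic_cline_decreases_eastward(self):
        df = make_frequency_sites(
            200, {"kind": "logistic_ew", "midpoint_lon": 10.0, "scale": 8.0,
                  "max_freq": 0.8}, seed=3, n_samples=200)
        west = df[df.lon < 0]["true_freq"].mean()
        east = df[df.lon > 20]["true_freq"].mean()
        assert west > east
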