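import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mthaplo.bayes import (CalibrationPrior, McmcSettings,
                           MonophylyConstraint, PosteriorTrace,
                           genealogies_from_trace, log_calibration_prior,
                           prior_from_mode_p95, relaxed_clock_loglik,
                           run_mcmc, summarize_ages, truncated_normal_prior)
from mthaplo.simulate import MutationModel
from mthaplo.tree import MutationTree, Node


class TestCalibrationPriors:
    def test_mode_p95_construction(self):
        p = prior_from_mode_p95("split", 45000.0, 60000.0)
        assert p.b == pytest.approx(np.log(20) / 15000.0)
        assert p.ppf(0.95) == pytest.approx(60000.0, abs=1e-6)
        assert p.pdf(44999.0) == 0.0
        assert p.pdf(45000.0) >= p.pdf(45001.0) > 0

    def test_second_calibration_point(self):
        p = prior_from_mode_p95("U6b1", 2300.0, 5000.0)
        assert p.ppf(0.95) == pytest.approx(5000.0, abs=1e-6)

    def test_density_maximal_at_mode_generic(self):
        for mode, p95 in [(8000.0, 14000.0), (1.0, 2.0)]:
            p = prior_from_mode_p95("c", mode, p95)
            xs = np.linspace(mode, p95 * 1.5, 200)
            dens = [p.pdf(x) for x in xs]
            assert np.argmax(dens) == 0

    def test_truncated_normal_integrates_and_peaks_at_centre(self):
        p = truncated_normal_prior("U5b3a1a", 5800.0, 1000.0)
        xs = np.linspace(0, 20000, 40001)
        mass = np.trapezoid([p.pdf(x) for x in xs], xs)
        assert mass == pytest.approx(1.0, abs=1e-6)
        assert p.pdf(5800.0) > p.pdf(5799.0)
        assert p.pdf(-1.0) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            prior_from_mode_p95("x", 10.0, 10.0)
        with pytest.raises(ValueError):
            truncated_normal_prior("x", 5.0, 0.0)


class TestLogPrior:
    def test_age_below_offset_is_minus_inf(self):
        priors = [prior_from_mode_p95("U6b1", 2300.0, 5000.0)]
        assert log_calibration_prior({"U6b1": 2000.0}, priors) == -np.inf
        assert np.isfinite(log_calibration_prior({"U6b1": 2400.0}, priors))

    def test_equals_sum_of_independent_densities(self):
        priors = [prior_from_mode_p95("a", 45000.0, 60000.0),
                  truncated_normal_prior("b", 5800.0, 1000.0)]
        ages = {"a": 47000.0, "b": 6100.0}
        want = sum(p.logpdf(ages[p.clade]) for p in priors)
        assert log_calibration_prior(ages, priors) == pytest.approx(want)

    def test_all_modes_is_finite_maximum_of_exponential_terms(self):
        priors = [prior_from_mode_p95("a", 45000.0, 60000.0),
                  prior_from_mode_p95("b", 2300.0, 5000.0)]
        at_mode = log_calibration_prior({"a": 45000.0, "b": 2300.0}, priors)
        assert np.isfinite(at_mode)
        assert at_mode >= log_calibration_prior({"a": 50000.0, "b": 3000.0},
                                                priors)


class TestRelaxedClockLikelihood:
    def _three_taxon(self):
        root = Node("root", time=3000.0)
        ab = Node("ab", time=1000.0)
        root.add(ab)
        root.add(Node("c", time=0.0))
        ab.add(Node("a", time=0.0))
        ab.add(Node("b", time=0.0))
        return MutationTree(root)

    def test_equal_rates_reduce_to_strict_clock(self):
        tree = self._three_taxon()
        aln = {"a": "ACGT", "b": "ACGA", "c": "GCGT"}
        strict = relaxed_clock_loglik(tree, 1.0, aln,
                                      clock_rate_per_site=1e-4)
        rates = {n.name: 1.0 for n in tree.preorder()}
        relaxed = relaxed_clock_loglik(tree, rates, aln,
                                       clock_rate_per_site=1e-4)
        assert relaxed == pytest.approx(strict, abs=1e-12)

    def test_matches_exhaustive_state_sum(self):
        import itertools
        from mthaplo.likelihood import hky_rate_matrix
        from scipy.linalg import expm

        tree = self._three_taxon()
        aln = {"a": "ACGT", "b": "ACGA", "c": "GCGT"}
        mm = MutationModel(kappa=5.0)
        mu = 2e-4
        got = relaxed_clock_loglik(tree, 1.0, aln, mm, mu, 1)
        # brute force over internal states
        Q = hky_rate_matrix(5.0, mm.base_freqs)
        nodes = {n.name: n for n in tree.preorder()}
        P = {name: expm(Q * (nodes[name].parent.time - nodes[name].time) * mu)
             for name in ("ab", "a", "b", "c")}
        idx = {b: i for i, b in enumerate("ACGT")}
        total = 0.0
        for site in range(4):
            s = 0.0
            for r_state, ab_state in itertools.product(range(4), range(4)):
                p = 0.25
                p *= P["ab"][r_state, ab_state]
                p *= P["c"][r_state, idx[aln["c"][site]]]
                p *= P["a"][ab_state, idx[aln["a"][site]]]
                p *= P["b"][ab_state, idx[aln["b"][site]]]
                s += p
            total += np.log(s)
        assert got == pytest.approx(total, abs=1e-10)


def tiny_alignment(tree, seed=0):
    from mthaplo.simulate import evolve_sequences
    from mthaplo.variants import synthetic_reference
    ref = synthetic_reference(200, seed=5)
    aln, _ = evolve_sequences(tree, ref, MutationModel(), 1 / 1000.0, seed)
    return aln


class TestMcmc:
    def test_identical_seeds_give_identical_traces(self, calibration_tree):
        priors = [prior_from_mode_p95("U5U6split", 45000.0, 60000.0)]
        aln = tiny_alignment(calibration_tree)
        kwargs = dict(
            priors=priors, settings=McmcSettings(iterations=4000,
                                                 thinning=10, burn_in=500,
                                                 seed=11),
            clock_rate_per_site=1e-7, track_clades=["U5U6split"])
        a = run_mcmc(calibration_tree, aln, **kwargs)
        b = run_mcmc(calibration_tree, aln, **kwargs)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_prior_only_reproduces_shifted_exponential(self,
                                                       calibration_tree):
        priors = [prior_from_mode_p95("U5U6split", 45000.0, 60000.0),
                  prior_from_mode_p95("U6b1", 2300.0, 5000.0)]
        trace = run_mcmc(calibration_tree, None, priors,
                         settings=McmcSettings(iterations=6000, thinning=3,
                                               burn_in=600, seed=4),
                         prior_only=True)
        for p in priors:
            _, pval = stats.kstest(trace.ages(p.clade), p._dist().cdf)
            assert pval > 0.01

    def test_constrained_clade_monophyletic_in_every_sample(
            self, calibration_tree):
        aln = tiny_alignment(calibration_tree)
        con = MonophylyConstraint("U6b1", frozenset({"t_u6b1_1",
                                                     "t_u6b1_2"}))
        trace = run_mcmc(calibration_tree, aln,
                         priors=[prior_from_mode_p95("U5U6split", 45000.0,
                                                     60000.0)],
                         constraints=[con],
                         settings=McmcSettings(iterations=3000, thinning=5,
                                               burn_in=300, seed=9),
                         sample_topology=True, clock_rate_per_site=1e-7)
        assert trace.samples["mono_U6b1"].all()
        assert len(trace.samples) > 100

    def test_nonbinary_topology_rejected(self):
        root = Node("r", time=10.0)
        for i in range(3):
            root.add(Node(f"t{i}", time=0.0))
        with pytest.raises(ValueError, match="binary"):
            run_mcmc(MutationTree(root), None, prior_only=True,
                     settings=McmcSettings(iterations=100, thinning=1,
                                           burn_in=10))

    def test_genealogies_from_trace_rebuild_heights(self, calibration_tree):
        aln = tiny_alignment(calibration_tree)
        trace = run_mcmc(calibration_tree, aln,
                         priors=[prior_from_mode_p95("U5U6split", 45000.0,
                                                     60000.0)],
                         settings=McmcSettings(iterations=3000, thinning=10,
                                               burn_in=300, seed=2),
                         clock_rate_per_site=1e-7, track_heights=True)
        gens = genealogies_from_trace(trace, calibration_tree,
                                      max_genealogies=5)
        assert len(gens) == 5
        for g in gens:
            for node in g.preorder():
                if node.parent is not None:
                    assert node.parent.time >= node.time


class TestSamplerProperties:
    def test_log_scale_walk_satisfies_detailed_balance(self):
        """pi(x) q(x->y) a(x->y) == pi(y) q(y->x) a(y->x) for the log-scale
        random-walk move used throughout (target: a calibration prior)."""
        p = prior_from_mode_p95("c", 2300.0, 5000.0)
        step = 0.4

        def q(x, y):  # lognormal proposal density of y around x
            z = (np.log(y) - np.log(x)) / step
            return np.exp(-0.5 * z * z) / (y * step * np.sqrt(2 * np.pi))

        def alpha(x, y):  # acceptance with the log-walk Hastings term
            return min(1.0, np.exp(p.logpdf(y) - p.logpdf(x)) * (y / x))

        for x, y in [(2500.0, 3100.0), (4000.0, 2600.0), (2301.0, 5000.0)]:
            flow_xy = p.pdf(x) * q(x, y) * alpha(x, y)
            flow_yx = p.pdf(y) * q(y, x) * alpha(y, x)
            assert flow_xy == pytest.approx(flow_yx, rel=1e-12)

    def test_tightening_a_prior_does_not_widen_its_posterior(
            self, calibration_tree):
        """Shrinking p95 - mode narrows (never widens) the clade's
        posterior interval on fixed data and seed, up to MC noise."""
        aln = tiny_alignment(calibration_tree)
        widths = []
        for p95 in (90000.0, 60000.0, 50000.0):
            trace = run_mcmc(
                calibration_tree, aln,
                priors=[prior_from_mode_p95("U5U6split", 45000.0, p95)],
                settings=McmcSettings(iterations=60000, thinning=20,
                                      burn_in=6000, seed=3),
                clock_rate_per_site=1e-7, track_clades=["U5U6split"])
            _, lo, hi = summarize_ages(trace, ["U5U6split"])["U5U6split"]
            widths.append(hi - lo)
        assert widths[1] <= widths[0] * 1.15
        assert widths[2] <= widths[1] * 1.15


class TestSummaries:
    def _trace(self, values):
        df = pd.DataFrame({"age_c": values})
        return PosteriorTrace(df, ("c",), McmcSettings(iterations=10,
                                                       thinning=1,
                                                       burn_in=1))

    def test_constant_trace(self):
        s = summarize_ages(self._trace([7.0] * 50), ["c"])
        assert s["c"] == (7.0, 7.0, 7.0)

    def test_order_statistics_on_1_to_1000(self):
        med, lo, hi = summarize_ages(self._trace(np.arange(1.0, 1001.0)),
                                     ["c"])["c"]
        assert med == pytest.approx(500.5)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_permutation_invariance_and_hpd_contains_median(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(3.0, 100.0, size=2000)
        a = summarize_ages(self._trace(vals), ["c"])
        b = summarize_ages(self._trace(rng.permutation(vals)), ["c"])
        assert a["c"][0] == b["c"][0]
        med, lo, hi = summarize_ages(self._trace(vals), ["c"],
                                     kind="hpd")["c"]
        assert lo <= med <= hi

    def test_missing_clade_errors(self):
        with pytest.raises(KeyError):
            summarize_ages(self._trace([1.0]), ["other"])
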