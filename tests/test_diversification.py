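import math

import numpy as np
import pytest
from scipy.stats import chi2

import salmodiv as sd
from salmodiv.io_formats import BranchingTimes
from oracles import bisse_loglik_bruteforce


class TestLtt:
    def test_three_tip_curve(self):
        curve = sd.ltt(sd.read_newick("((A:1,B:1):1,C:2);"))
        assert curve.ages.tolist() == [2.0, 1.0]
        assert curve.counts.tolist() == [2, 3]

    def test_comb_tree_steps(self):
        tree = sd.read_newick("(A:4,(B:3,(C:2,(D:1,E:1):1):1):1);")
        curve = sd.ltt(tree)
        assert len(curve.ages) == 4  # n - 1 steps
        assert curve.n_tips == 5

    def test_count_at_step_semantics(self):
        curve = sd.ltt(sd.read_newick("((A:1,B:1):1,C:2);"))
        assert curve.count_at(2.5) == 1
        assert curve.count_at(1.5) == 2
        assert curve.count_at(0.2) == 3


class TestGamma:
    def test_hand_example(self):
        bt = BranchingTimes.from_times([2.0, 1.0])
        res = sd.gamma_test(bt)
        assert res.gamma == pytest.approx(-0.5 / (5.0 * math.sqrt(1.0 / 12.0)))
        assert res.gamma == pytest.approx(-0.3464, abs=2e-4)

    def test_tip_heavy_tree_gives_positive_gamma(self):
        """Branching concentrated near the present pushes gamma positive,
        the recent-speciation signature."""
        times = [10.0] + [0.5 - 0.01 * i for i in range(20)]
        res = sd.gamma_test(BranchingTimes.from_times(times))
        assert res.gamma > 2.0
        assert res.p_two_tailed < 0.05

    def test_root_heavy_tree_gives_negative_gamma(self):
        times = [10.0 - 0.01 * i for i in range(20)] + [0.5]
        assert sd.gamma_test(BranchingTimes.from_times(times)).gamma < -2.0


class TestSurvivalModels:
    def test_model_a_closed_form(self):
        comp = sd.fit_survival(BranchingTimes.from_times([1.0, 2.0, 3.0]))
        assert comp.fit_a.params["delta"] == pytest.approx(0.5)
        assert comp.fit_a.loglik == pytest.approx(3 * math.log(0.5) - 3.0)

    def test_nesting_and_weights(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(2.0, size=60)
        comp = sd.fit_survival(BranchingTimes.from_times(x))
        assert comp.fit_b.loglik >= comp.fit_a.loglik - 1e-9
        assert comp.fit_c.loglik >= comp.fit_a.loglik - 1e-9
        w = comp.akaike_weights
        assert w["B"] + w["C"] == pytest.approx(1.0)

    def test_fixed_breakpoint_mode(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(2.0, size=50)
        comp = sd.fit_survival(BranchingTimes.from_times(x), breakpoint=2.7)
        assert comp.breakpoint_mode == "fixed"
        assert comp.fit_c.params["tc"] == 2.7
        assert comp.lrt_ac.df == 1

    def test_profiled_breakpoint_finds_true_shift(self):
        """A genuine hazard shift is located near its true age."""
        rng = np.random.default_rng(7)
        # recent regime: fast hazard below 3 Ma; older regime much slower
        recent = rng.uniform(0.0, 3.0, size=150)
        old = 3.0 + rng.exponential(8.0, size=40)
        with pytest.warns(RuntimeWarning, match="profiled"):
            comp = sd.fit_survival(
                BranchingTimes.from_times(np.concatenate([recent, old]))
            )
        assert comp.breakpoint_mode == "profile"
        assert comp.lrt_ac.df == 2
        assert 2.0 < comp.fit_c.params["tc"] < 4.5

    def test_weibull_shape_below_one_for_recent_diversification(self):
        rng = np.random.default_rng(8)
        x = rng.weibull(0.68, size=200) * 5.0
        comp = sd.fit_survival(BranchingTimes.from_times(x))
        assert comp.fit_b.params["beta"] < 1.0

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            sd.fit_survival(BranchingTimes.from_times([0.0, 1.0, 2.0]))


class TestAkaikeWeights:
    def test_equal_aic_equal_weights(self):
        w = sd.akaike_weights([-10.0, -10.0], [2, 2])
        assert np.allclose(w, [0.5, 0.5])

    def test_delta_two_example(self):
        # AIC difference of 2: weights 0.731 / 0.269
        w = sd.akaike_weights([-10.0, -11.0], [2, 2])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert w.sum() == pytest.approx(1.0)


class TestBisseLoglik:
    def test_zero_extinction_matches_brute_force(self):
        tree = sd.simulate_bd_tree(0.5, 0.0, 5, seed=3)
        traits = sd.TraitTable(
            {l.taxon.label: i % 2 for i, l in enumerate(tree.leaf_node_iter())}
        )
        p = sd.BisseParams(0.5, 0.3, 0.0, 0.0, 0.1, 0.1)
        a = sd.bisse_loglik(tree, traits, p)
        b = bisse_loglik_bruteforce(tree, traits, p, step=1e-3)
        assert a == pytest.approx(b, abs=1e-5)

    def test_tiny_branch_two_tip_euler(self):
        tree = sd.read_newick("(A:1e-08,B:1e-08);")
        traits = sd.TraitTable({"A": 0, "B": 1})
        p = sd.BisseParams(0.4, 0.6, 0.1, 0.2, 0.3, 0.2)
        a = sd.bisse_loglik(tree, traits, p, root_mode="equal")
        b = bisse_loglik_bruteforce(
            tree, traits, p, root_mode="equal", step=1e-9, scheme="euler"
        )
        assert a == pytest.approx(b, abs=1e-5)

    def test_likelihood_invariant_to_rotation(self):
        tree = sd.simulate_bd_tree(0.5, 0.1, 8, seed=4)
        traits = sd.TraitTable(
            {l.taxon.label: i % 2 for i, l in enumerate(tree.leaf_node_iter())}
        )
        p = sd.BisseParams(0.5, 0.3, 0.1, 0.05, 0.1, 0.2)
        base = sd.bisse_loglik(tree, traits, p)
        rotated = tree.clone(depth=1)
        for node in rotated.preorder_internal_node_iter():
            node.set_child_nodes(node.child_nodes()[::-1])
        assert sd.bisse_loglik(rotated, traits, p) == pytest.approx(base, abs=1e-9)

    def test_missing_trait_rejected(self):
        tree = sd.read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="trait"):
            sd.bisse_loglik(
                tree, sd.TraitTable({"A": 0, "B": 1}), sd.BisseParams(1, 1, 0, 0, 0.1, 0.1)
            )

    def test_non_ultrametric_rejected(self):
        tree = sd.read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            sd.bisse_loglik(
                tree,
                sd.TraitTable({"A": 0, "B": 1, "C": 0}),
                sd.BisseParams(1, 1, 0, 0, 0.1, 0.1),
            )


class TestBisseMl:
    def test_nesting_holds(self):
        truth = sd.BisseParams(0.2, 0.5, 0.05, 0.1, 0.03, 0.03)
        tree, traits = sd.simulate_bisse(truth, 25, root_state=1, seed=12)
        constrained = sd.bisse_ml(tree, traits, constrained=True, n_starts=2, seed=0)
        free = sd.bisse_ml(
            tree, traits, n_starts=2, seed=0, extra_starts=[constrained.params]
        )
        assert free.loglik >= constrained.loglik - 1e-6
        assert constrained.params.lam0 == constrained.params.lam1
        assert constrained.params.mu0 == constrained.params.mu1
        res = sd.bisse_lrt(free, constrained)
        assert res.df == 2
        assert res.statistic >= 0.0

    def test_lrt_reference_values(self):
        """Chi-square tail areas used for the LRT: 11.4 on df=2 vs df=1
        (the df=1 reading matches a printed p of 0.0008), and 18.44 on df=1."""
        assert chi2.sf(11.4, 2) == pytest.approx(0.00335, abs=2e-5)
        assert chi2.sf(11.4, 1) == pytest.approx(0.00073, abs=2e-5)
        assert chi2.sf(18.44, 1) < 1e-4

    def test_lrt_equal_fits(self):
        fit = sd.BisseFit(
            sd.BisseParams(1, 1, 0, 0, 0.1, 0.1), -10.0, False, 6, True
        )
        null = sd.BisseFit(
            sd.BisseParams(1, 1, 0, 0, 0.1, 0.1), -10.0, True, 4, True
        )
        res = sd.bisse_lrt(fit, null)
        assert res.statistic == 0.0 and res.pvalue == 1.0


class TestBisseMcmc:
    def test_seed_determinism(self):
        truth = sd.BisseParams(0.2, 0.5, 0.02, 0.02, 0.05, 0.05)
        tree, traits = sd.simulate_bisse(truth, 12, root_state=1, seed=2)
        t1 = sd.bisse_mcmc(tree, traits, n_steps=200, seed=5, min_ess=0)
        t2 = sd.bisse_mcmc(tree, traits, n_steps=200, seed=5, min_ess=0)
        assert np.array_equal(t1.samples, t2.samples)
        assert t1.burnin == 20

    def test_posterior_summaries_consistent(self):
        truth = sd.BisseParams(0.2, 0.5, 0.02, 0.02, 0.05, 0.05)
        tree, traits = sd.simulate_bisse(truth, 12, root_state=1, seed=2)
        trace = sd.bisse_mcmc(tree, traits, n_steps=400, seed=1, min_ess=0)
        assert trace.samples.shape == (400, 6)
        for j in range(6):
            assert trace.ci95[j, 0] <= trace.posterior_mean[j] <= trace.ci95[j, 1]

    def test_contrasting_rates_ordered(self):
        """Posterior mean speciation rates reflect a strong simulated
        contrast between the two states."""
        truth = sd.BisseParams(0.05, 0.6, 0.0, 0.0, 0.03, 0.03)
        tree, traits = sd.simulate_bisse(truth, 40, root_state=1, seed=21)
        trace = sd.bisse_mcmc(tree, traits, n_steps=1200, seed=3, min_ess=0)
        lam0_mean = trace.posterior_mean[0]
        lam1_mean = trace.posterior_mean[1]
        assert lam1_mean > lam0_mean
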