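import numpy as np
import pytest

from microcause.cohort import CohortConfig, EffectSpec, simulate_cohort
from microcause.composition import distance, distance_to_kernel
from microcause.diversity import (betta_coefficient, bootstrap_se,
                                  chao1_richness, diversity_randomization_test,
                                  estimate_diversity, mirkat_score,
                                  observed_richness, plugin_shannon,
                                  beta_diversity_test)
from microcause.matching import MatchedDesign
from microcause.randomization import generate_assignments

from oracles import betta_oracle


class TestShannon:
    def test_uniform_gives_log_a(self):
        assert plugin_shannon(np.ones(8)) == pytest.approx(np.log(8))

    def test_single_taxon_zero(self):
        assert plugin_shannon(np.array([0, 9, 0])) == 0.0

    def test_hand_arithmetic(self):
        # (1,1,2): -(1/4 log 1/4 + 1/4 log 1/4 + 1/2 log 1/2) = 1.5 log 2
        assert plugin_shannon(np.array([1, 1, 2])) == \
            pytest.approx(1.5 * np.log(2))

    def test_bounded_by_log_richness(self, null_sim):
        for row in null_sim.counts.counts[:10]:
            assert plugin_shannon(row) <= np.log(observed_richness(row)) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            plugin_shannon(np.zeros(3))


class TestChao1:
    def test_no_singletons_or_doubletons(self):
        row = np.array([5, 9, 3])
        est, se = chao1_richness(row)
        assert est == 3.0 and se == 0.0

    def test_formula_arithmetic(self):
        # f1 = 4, f2 = 2, S_obs = 10 -> 10 + 16/4 = 14
        row = np.array([1, 1, 1, 1, 2, 2, 5, 6, 7, 8])
        est, se = chao1_richness(row)
        assert est == pytest.approx(14.0)
        # classical variance: f2 (r^2/2 + r^3 + r^4/4) with r = 2
        assert se == pytest.approx(np.sqrt(2 * (2 + 8 + 4)))

    def test_estimate_at_least_observed(self, null_sim):
        for row in null_sim.counts.counts[:10]:
            est, _ = chao1_richness(row)
            assert est >= observed_richness(row)

    def test_bias_corrected_when_no_doubletons(self):
        row = np.array([1, 1, 1, 5, 9])
        est, _ = chao1_richness(row)
        assert est == pytest.approx(5 + 3 * 2 / 2)


class TestBootstrapSE:
    def test_deterministic_statistic_zero_se(self):
        se = bootstrap_se(np.array([10, 20, 30]), lambda r: float(r.sum()),
                          n_boot=60, seed=0)
        assert se == 0.0

    def test_reproducible(self):
        row = np.array([5, 10, 3, 8])
        a = bootstrap_se(row, plugin_shannon, n_boot=100, seed=3)
        b = bootstrap_se(row, plugin_shannon, n_boot=100, seed=3)
        assert a == b

    def test_se_shrinks_with_depth(self):
        # Shannon SE shrinks ~1/sqrt(depth) for a non-uniform composition
        # (at the uniform entropy maximum the first-order term vanishes)
        shallow = bootstrap_se(np.array([30, 70]), plugin_shannon,
                               n_boot=400, seed=1)
        deep = bootstrap_se(np.array([3000, 7000]), plugin_shannon,
                            n_boot=400, seed=1)
        assert 5 < shallow / deep < 20

    def test_minimum_boot(self):
        with pytest.raises(ValueError):
            bootstrap_se(np.array([5, 5]), plugin_shannon, n_boot=10)


class TestBetta:
    def test_ols_degeneracy(self):
        # all sigma_i = 0 on exactly linear data -> OLS coefficient
        w = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        y = 2.0 + 3.0 * w
        beta1 = betta_coefficient(y, np.zeros(6), w)
        assert beta1 == pytest.approx(3.0, abs=1e-10)

    def test_equal_groups_zero(self):
        w = np.array([1, 1, 0, 0], dtype=float)
        y = np.array([4.0, 6.0, 4.0, 6.0])
        ses = np.full(4, 0.5)
        assert betta_coefficient(y, ses, w) == pytest.approx(0.0, abs=1e-10)

    def test_six_sample_oracle(self):
        w = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        y = np.array([5.2, 6.8, 5.9, 4.1, 3.6, 4.9])
        ses = np.array([0.3, 0.9, 0.2, 0.5, 0.1, 0.7])
        got = betta_coefficient(y, ses, w)
        expected = betta_oracle(y, ses, w)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_singular_design_rejected(self):
        w = np.array([1, 1, 0, 0], dtype=float)
        with pytest.raises(ValueError, match="singular"):
            betta_coefficient(np.ones(4), np.ones(4) * 0.1, w,
                              covariates=w.copy())

    def test_needs_two_per_arm(self):
        with pytest.raises(ValueError):
            betta_coefficient(np.ones(3), np.ones(3), np.array([1., 0, 0]))


class TestMirkat:
    def test_zero_kernel(self):
        assert mirkat_score(np.zeros((4, 4)), np.array([1, 1, 0, 0])) == 0.0

    def test_uncentered_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            mirkat_score(np.eye(4), np.array([1, 1, 0, 0]))

    def test_orthogonal_residual_zero(self):
        # kernel whose range excludes the centered w
        v = np.array([1.0, -1.0, 1.0, -1.0])
        K = np.outer(v, v)           # centered: rows sum to 0
        w = np.array([1.0, 1.0, 0.0, 0.0])
        assert mirkat_score(K, w) == pytest.approx(0.0, abs=1e-10)

    def test_four_sample_hand_quadratic_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        K, _ = distance_to_kernel(d)
        w = np.array([1.0, 0.0, 1.0, 0.0])
        r = w - 0.5
        expected = sum(r[i] * K[i, j] * r[j]
                       for i in range(4) for j in range(4))
        assert mirkat_score(K, w) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_shifting_w(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        K, _ = distance_to_kernel(d)
        w = np.array([1.0, 0, 1, 0, 1, 0])
        assert mirkat_score(K, w) == pytest.approx(mirkat_score(K, w + 5.0))


class TestDiversityTest:
    def test_pair_order_invariance(self, null_sim):
        pairs = list(zip(null_sim.cohort.exposed_ids,
                         null_sim.cohort.control_ids))[:8]
        d1 = MatchedDesign(pairs=pairs)
        d2 = MatchedDesign(pairs=pairs[::-1])
        a1 = generate_assignments(d1, 256, seed=0)   # exhaustive, 2^8
        a2 = generate_assignments(d2, 256, seed=0)
        r1 = diversity_randomization_test(null_sim.counts, d1, a1,
                                          which="richness")
        r2 = diversity_randomization_test(null_sim.counts, d2, a2,
                                          which="richness")
        # the null distributions coincide as multisets; exactly tied Chao1
        # estimates can split either way at float precision, moving p by at
        # most one grid step
        assert np.allclose(np.sort(r1.null), np.sort(r2.null), atol=1e-9)
        assert abs(r1.p - r2.p) <= 1 / a1.n_iter + 1e-12

    def test_evenness_effect_detected(self):
        # sharpened latent means under exposure -> lower Shannon diversity
        cfg = CohortConfig(n_units_exposed=100, n_units_control=100,
                           n_taxa=40, seed=3,
                           effect_spec=EffectSpec(diversity_shift=0.4))
        sim = simulate_cohort(cfg)
        design = MatchedDesign(pairs=list(zip(sim.cohort.exposed_ids,
                                              sim.cohort.control_ids)))
        assignments = generate_assignments(design, 400, seed=3)
        res = diversity_randomization_test(sim.counts, design, assignments,
                                           which="shannon", n_boot=60, seed=3)
        assert res.observed < 0          # exposed less diverse
        assert res.p <= 0.02

    def test_external_estimates_injected(self, null_sim, null_design,
                                         null_assignments):
        import pandas as pd
        ids = null_design.sample_order()
        ext = pd.DataFrame({"estimate": np.linspace(1, 2, len(ids)),
                            "se": np.full(len(ids), 0.1)},
                           index=pd.Index(null_sim.counts.sample_ids,
                                          name="sample_id"))
        res = diversity_randomization_test(null_sim.counts, null_design,
                                           null_assignments, which="shannon",
                                           external=ext)
        assert res.extras["estimator"] == "external"


class TestBetaDiversityTest:
    def test_four_metric_battery(self, null_sim, null_design,
                                 null_assignments):
        res = beta_diversity_test(null_sim.counts, null_design,
                                  null_assignments,
                                  metrics=("aitchison", "jaccard",
                                           "gower_clr", "unifrac_unweighted"),
                                  tree=null_sim.tree_newick)
        assert set(res) == {"aitchison", "jaccard", "gower_clr",
                            "unifrac_unweighted"}
        for r in res.values():
            assert 0 < r.p <= 1
            assert r.p_adjusted >= r.p - 1e-12

    def test_q_observed_matches_direct(self, null_sim, null_design,
                                       null_assignments):
        res = beta_diversity_test(null_sim.counts, null_design,
                                  null_assignments, metrics=("aitchison",))
        sub = null_sim.counts.subset_samples(null_design.sample_order())
        K, _ = distance_to_kernel(distance(sub, "aitchison"))
        w = np.r_[np.ones(null_design.n_pairs), np.zeros(null_design.n_pairs)]
        assert res["aitchison"].observed == pytest.approx(
            mirkat_score(K, w), rel=1e-10)
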