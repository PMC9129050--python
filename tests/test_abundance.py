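import numpy as np
import pandas as pd
import pytest

from microcause.abundance import (differential_abundance_test,
                                  logfold_statistic, normalize_by_ratio,
                                  select_references, tm_statistic,
                                  compositional_mean_test, ReferenceSet)
from microcause.composition import clr_transform
from microcause.io import CountMatrix
from microcause.matching import MatchedDesign
from microcause.randomization import generate_assignments


def _clr_from_values(values):
    """Wrap hand-built CLR-like rows (each summing to zero)."""
    from microcause.composition import ClrMatrix
    values = np.asarray(values, dtype=float)
    return ClrMatrix(values=values, sample_ids=[f"s{i}" for i in
                                                range(values.shape[0])],
                     taxon_ids=[f"t{j}" for j in range(values.shape[1])],
                     pseudocount=0.0)


class TestTmStatistic:
    def test_identical_arms_zero(self):
        L = _clr_from_values([[1.0, -1.0], [0.5, -0.5]] * 2)
        t, _ = tm_statistic(L, np.array([1, 1, 0, 0]))
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # taxon a: exposed (1, 3), control (0, 2); means 2 vs 1, diff^2 = 1
        # within-arm deviations +-1 in each arm -> pooled (ML) variance
        # (1+1+1+1)/4 = 1; factor = 2*2/4 = 1 -> T_M = 1 (same for taxon b)
        L = _clr_from_values([[1, -1], [3, -3], [0, 0], [2, -2]])
        t, argmax = tm_statistic(L, np.array([1, 1, 0, 0]))
        assert t == pytest.approx(1.0, abs=1e-12)

    def test_duplication_doubles(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(6, 4))
        vals = raw - raw.mean(axis=1, keepdims=True)
        w = np.array([1, 1, 1, 0, 0, 0])
        t1, _ = tm_statistic(_clr_from_values(vals), w)
        t2, _ = tm_statistic(_clr_from_values(np.vstack([vals, vals])),
                             np.r_[w, w])
        assert t2 == pytest.approx(2 * t1, rel=1e-10)

    def test_scale_invariance_via_counts(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 60, size=(8, 5)).astype(float)
        scales = rng.uniform(0.5, 4.0, size=8)
        w = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        t1, _ = tm_statistic(clr_transform(counts, 0), w)
        t2, _ = tm_statistic(clr_transform(counts * scales[:, None], 0), w)
        assert t1 == pytest.approx(t2, rel=1e-10)

    def test_degenerate_taxon_with_shift_errors(self):
        # zero pooled variance but nonzero mean difference
        L = _clr_from_values([[1, -1], [1, -1], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="zero pooled"):
            tm_statistic(L, np.array([1, 1, 0, 0]))

    def test_one_arm_empty_rejected(self):
        L = _clr_from_values([[1.0, -1.0], [0.5, -0.5]])
        with pytest.raises(ValueError):
            tm_statistic(L, np.array([1, 1]))


class TestSelectReferences:
    def test_depth_proportional_taxon_has_minimal_dispersion(self):
        # taxon 0 is an exact, noise-free share of the sequencing depth;
        # the others carry extra lognormal noise, so taxon 0 attains the
        # smallest dispersion score and is selected
        rng = np.random.default_rng(0)
        depth = rng.integers(5_000, 20_000, size=16).astype(float)
        props = np.array([0.4, 0.3, 0.2, 0.1])
        noise = np.exp(rng.normal(0.0, 0.5, size=(16, 3)))
        counts = np.column_stack(
            [depth * props[0]] + [depth * props[j + 1] * noise[:, j]
                                  for j in range(3)]).round().astype(int)
        cm = CountMatrix(counts, [f"s{i}" for i in range(16)],
                         ["prop", "x", "y", "z"])
        refs = select_references(cm, dispersion_threshold=0.6,
                                 prevalence_threshold=0.5, pseudocount=1)
        assert "prop" in refs.taxon_ids
        assert refs.scores["dispersion"].idxmin() == "prop"

    def test_proportional_pair_zero_dispersion_contribution(self):
        base = np.arange(1, 9, dtype=float)
        counts = np.column_stack([base * 3, base * 5])
        cm = CountMatrix(counts.astype(int) * 10, [f"s{i}" for i in range(8)],
                         ["a", "b"])
        refs = select_references(cm, 1.0, 0.5, pseudocount=0)
        assert refs.scores.loc["a", "dispersion"] == pytest.approx(0.0)

    def test_low_prevalence_excluded(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(5, 50, size=(10, 3))
        counts[3:, 2] = 0       # taxon c in 30% of samples
        cm = CountMatrix(counts, [f"s{i}" for i in range(10)],
                         ["a", "b", "c"])
        refs = select_references(cm, dispersion_threshold=50.0,
                                 prevalence_threshold=0.9)
        assert "c" not in refs.taxon_ids

    def test_toy_scores_match_direct_enumeration(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(8, 4))
        counts[:, 0] += 1
        cm = CountMatrix(counts, [f"s{i}" for i in range(8)], list("abcd"))
        refs = select_references(cm, 100.0, 0.01, pseudocount=1.0)
        logc = np.log(counts + 1.0)
        for j, t in enumerate("abcd"):
            sds = []
            for j2 in range(4):
                if j2 == j:
                    continue
                sds.append(np.std(logc[:, j] - logc[:, j2], ddof=1))
            assert refs.scores.loc[t, "dispersion"] == \
                pytest.approx(np.median(sds))

    def test_relaxation_covers_every_sample(self):
        # selected taxon absent from one sample forces relaxation
        counts = np.array([[9, 5, 1], [9, 5, 1], [9, 5, 1], [0, 5, 9]])
        counts[:3, 2] = [1, 1, 1]
        cm = CountMatrix(counts, [f"s{i}" for i in range(4)], list("abc"))
        refs = select_references(cm, dispersion_threshold=0.2,
                                 prevalence_threshold=0.5)
        ridx = [cm.taxon_ids.index(r) for r in refs.taxon_ids]
        assert (cm.counts[:, ridx].sum(axis=1) > 0).all()


class TestNormalizeByRatio:
    def _setup(self):
        counts = np.array([[0, 4, 5], [3, 4, 5], [9, 4, 5]])
        cm = CountMatrix(counts, ["s0", "s1", "s2"], ["a", "r1", "r2"])
        refs = ReferenceSet(taxon_ids=["r1", "r2"], scores=pd.DataFrame())
        return cm, refs

    def test_zero_count_zero(self):
        cm, refs = self._setup()
        v = normalize_by_ratio(cm, "a", refs)
        assert v[0] == 0.0

    def test_equal_to_reference_half(self):
        cm, refs = self._setup()
        assert normalize_by_ratio(cm, "a", refs)[2] == pytest.approx(0.5)

    def test_arithmetic(self):
        cm, refs = self._setup()
        assert normalize_by_ratio(cm, "a", refs)[1] == pytest.approx(0.25)

    def test_bounds_and_monotonicity(self):
        cm, refs = self._setup()
        v = normalize_by_ratio(cm, "a", refs)
        assert ((v >= 0) & (v <= 1)).all()
        assert v[0] < v[1] < v[2]

    def test_reference_taxon_rejected(self):
        cm, refs = self._setup()
        with pytest.raises(ValueError, match="reference"):
            normalize_by_ratio(cm, "r1", refs)


class TestLogFold:
    def test_identical_arms_zero(self):
        v = np.array([0.2, 0.4, 0.2, 0.4])
        assert logfold_statistic(v, np.array([1, 1, 0, 0]), 1e-6) == \
            pytest.approx(0.0)

    def test_doubled_values_log_two(self):
        v = np.array([0.2, 0.4, 0.1, 0.2])
        got = logfold_statistic(v, np.array([1, 1, 0, 0]), 1e-12)
        assert got == pytest.approx(np.log(2), abs=1e-6)

    def test_six_sample_hand_table(self):
        v = np.array([0.1, 0.2, 0.3, 0.05, 0.1, 0.15])
        w = np.array([1, 1, 1, 0, 0, 0])
        eps = 0.01
        expected = np.mean(np.log(v[:3] + eps)) - np.mean(np.log(v[3:] + eps))
        assert logfold_statistic(v, w, eps) == pytest.approx(expected)

    def test_eps_required(self):
        with pytest.raises(ValueError):
            logfold_statistic(np.ones(4), np.array([1, 1, 0, 0]), 0.0)


class TestCompositionalMeanTest:
    def test_asv_rank_equals_no_aggregation(self, null_sim, null_design,
                                            null_assignments):
        res = compositional_mean_test(null_sim.counts, null_design,
                                      null_assignments, ranks=("ASV",))
        sub = null_sim.counts.subset_samples(null_design.sample_order())
        L = clr_transform(sub, 1.0)
        w = np.r_[np.ones(null_design.n_pairs), np.zeros(null_design.n_pairs)]
        t_direct, _ = tm_statistic(L, w)
        assert res["ASV"].observed == pytest.approx(t_direct, rel=1e-12)

    def test_genus_rank_runs(self, null_sim, null_design, null_assignments):
        res = compositional_mean_test(null_sim.counts, null_design,
                                      null_assignments, ranks=("Genus",))
        assert 0 < res["Genus"].p <= 1


class TestDifferentialAbundanceTest:
    def test_reference_taxa_excluded(self, null_sim, null_design,
                                     null_assignments):
        sub = null_sim.counts.subset_samples(null_design.sample_order())
        refs = select_references(sub, 0.8, 0.6)
        table = differential_abundance_test(null_sim.counts, null_design,
                                            null_assignments, refs=refs)
        assert not set(table.taxon) & set(refs.taxon_ids)
        assert (table.p_adj >= table.p - 1e-12).all()
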