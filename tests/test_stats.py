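from itertools import combinations

import numpy as np
import pytest

from connfp import (CohortConfig, EffectSpec, PermutationConfig,
                    generate_cohort, null_volume_params, permutation_test,
                    select_features)
from connfp.stats import PermutationTable


def _two_group_cfg(**kw):
    defaults = dict(n_permutations=5000, correction="none",
                    comparisons=(("A", "B"),), seed=0)
    defaults.update(kw)
    return PermutationConfig(**defaults)


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        block = np.arange(12.0).reshape(4, 3)
        features = np.vstack([block, block])
        labels = ["A"] * 4 + ["B"] * 4
        table = permutation_test(features, labels, _two_group_cfg())
        np.testing.assert_array_equal(table.observed, 0.0)
        np.testing.assert_array_equal(table.p_values, 1.0)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 3-vs-3, one region: only 20 distinct assignments of subjects to A
        values = np.array([0.3, 1.1, 2.0, 2.4, 3.3, 4.1])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        observed = abs(values[:3].mean() - values[3:].mean())
        exact_count = sum(
            abs(values[list(idx)].mean()
                - values[[i for i in range(6) if i not in idx]].mean())
            >= observed - 1e-12
            for idx in combinations(range(6), 3))
        exact_p = exact_count / 20
        table = permutation_test(values[:, None], labels, _two_group_cfg())
        assert table.p_values[0, 0] == pytest.approx(exact_p, abs=0.02)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        features = rng.standard_normal((24, 4))
        labels = ["NC"] * 8 + ["MCI"] * 8 + ["AD"] * 8
        cfg = PermutationConfig(n_permutations=500, seed=42)
        t1 = permutation_test(features, labels, cfg)
        t2 = permutation_test(features, labels, cfg)
        np.testing.assert_array_equal(t1.p_values, t2.p_values)

    def test_maxt_at_least_as_conservative_as_uncorrected(self):
        rng = np.random.default_rng(1)
        features = rng.standard_normal((30, 6))
        features[:10] += rng.normal(0, 0.5, 6)  # some signal in NC
        labels = ["NC"] * 10 + ["MCI"] * 10 + ["AD"] * 10
        kw = dict(n_permutations=1000, seed=5)
        p_maxt = permutation_test(features, labels,
                                  PermutationConfig(correction="maxT", **kw)).p_values
        p_none = permutation_test(features, labels,
                                  PermutationConfig(correction="none", **kw)).p_values
        assert (p_maxt >= p_none - 1e-12).all()

    def test_p_value_range(self):
        rng = np.random.default_rng(2)
        features = rng.standard_normal((20, 3))
        features[:6, 0] += 10.0  # overwhelming effect in one region
        labels = ["A"] * 6 + ["B"] * 14
        table = permutation_test(features, labels, _two_group_cfg(n_permutations=200))
        assert table.p_values.min() >= 1 / 201
        assert table.p_values.max() <= 1.0

    def test_observed_stat_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        features = rng.standard_normal((18, 4))
        labels = np.array(["A"] * 6 + ["B"] * 12)
        perm = rng.permutation(18)
        t1 = permutation_test(features, labels, _two_group_cfg(n_permutations=200))
        t2 = permutation_test(features[perm], labels[perm],
                              _two_group_cfg(n_permutations=200))
        np.testing.assert_allclose(t1.observed, t2.observed, atol=1e-12)

    def test_welch_statistic_downweights_high_variance_regions(self):
        rng = np.random.default_rng(4)
        features = np.column_stack([rng.normal(0, 1, 20), rng.normal(0, 100, 20)])
        features[:10, 0] += 2.0
        labels = ["A"] * 10 + ["B"] * 10
        table = permutation_test(features, labels,
                                 _two_group_cfg(statistic="welch_t",
                                                n_permutations=500))
        assert table.observed[0, 0] > table.observed[0, 1]

    def test_larger_planted_volume_shift_gives_smaller_p(self):
        base = dict(n_per_group={"NC": 10, "MCI": 10, "AD": 10}, n_rois=10,
                    n_timepoints=20, volume_params=null_volume_params())
        hip = 4  # Hippocampus_L among the 10 target ROIs
        mean_p = {}
        for shift in (0.0, 1.0):
            effects = ([] if shift == 0.0 else
                       [EffectSpec("AD", hip, "volume_shift", -shift)])
            ps = []
            for seed in range(20):
                cohort = generate_cohort(CohortConfig(seed=seed, group_effects=effects,
                                                      **base))
                table = permutation_test(
                    cohort.volumes_matrix(), cohort.labels,
                    PermutationConfig(n_permutations=300, correction="none",
                                      seed=seed))
                ps.append(table.p_values[1, hip])  # NC vs AD
            mean_p[shift] = np.mean(ps)
        assert mean_p[1.0] < mean_p[0.0]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test(np.zeros((3, 2)), ["A", "B", "B"], _two_group_cfg())


class TestSelectFeatures:
    def _table(self, modality, region_names, p_rows):
        p = np.array(p_rows)  # comparisons x regions
        r = len(region_names)
        zeros = np.zeros(r)
        return PermutationTable(modality, list(region_names),
                                [("NC", "MCI"), ("NC", "AD"), ("MCI", "AD")],
                                np.zeros_like(p), p,
                                {g: zeros for g in ("NC", "MCI", "AD")},
                                {g: zeros for g in ("NC", "MCI", "AD")},
                                5000, "maxT")

    def test_rule_application(self):
        t = self._table("volume", ["a", "b"],
                        [[0.02, 0.02], [0.03, 0.30], [0.30, 0.30]])
        sel = select_features({"volume": t})
        assert sel.selected == [("volume", "a")]

    def test_published_style_pvalue_fixture(self):
        """Selection replays the reported corrected p-value tables."""
        regions = ["Thalamus_L", "Thalamus_R", "Putamen_L", "Putamen_R",
                   "Hippocampus_L", "Hippocampus_R", "Caudate_L", "Caudate_R",
                   "Amygdala_L", "Amygdala_R"]
        volume_p = np.array([  # NC/MCI, NC/AD, MCI/AD rows
            [0.241, 0.131, 0.020, 0.054, 0.071, 0.039, 0.368, 0.386, 0.055, 0.669],
            [0.028, 0.035, 0.001, 0.015, 0.0009, 0.0009, 0.165, 0.247, 0.002, 0.078],
            [0.064, 0.143, 0.130, 0.254, 0.0009, 0.001, 0.200, 0.306, 0.066, 0.024]])
        centrality_p = np.array([
            [0.139, 0.125, 0.637, 0.878, 0.015, 0.115, 0.420, 0.373, 0.100, 0.716],
            [0.032, 0.233, 0.021, 0.534, 0.017, 0.545, 0.022, 0.361, 0.234, 0.240],
            [0.226, 0.613, 0.013, 0.166, 0.324, 0.849, 0.061, 0.421, 0.671, 0.124]])
        sel = select_features({
            "volume": self._table("volume", regions, volume_p),
            "centrality": self._table("centrality", regions, centrality_p)})
        assert set(sel.selected) == {
            ("volume", "Putamen_L"), ("volume", "Hippocampus_L"),
            ("volume", "Hippocampus_R"),
            ("centrality", "Putamen_L"), ("centrality", "Hippocampus_L")}
        assert ("centrality", "Thalamus_L") not in sel.selected

    def test_empty_selection_warns(self):
        t = self._table("volume", ["a"], [[0.5], [0.5], [0.5]])
        with pytest.warns(UserWarning, match="no feature"):
            sel = select_features({"volume": t})
        assert not sel


def test_config_validation():
    with pytest.raises(ValueError):
        PermutationConfig(n_permutations=10)
    with pytest.raises(ValueError):
        PermutationConfig(alpha=1.5)
    with pytest.raises(ValueError):
        PermutationConfig(correction="bonferroni")
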