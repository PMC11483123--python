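import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesiclefuse.stats import (compare, describe, dunn_test,
                               normalize_to_control, screen)

# canned 3-group data; reference statistics computed with R 4.3
# (stats::kruskal.test, stats::wilcox.test exact, and Dunn's z/p written
# from the rank formula) and frozen here
GROUP_A = [12, 15, 14, 11, 39, 40, 41, 38, 42]
GROUP_B = [18, 17, 21, 44, 43, 45, 46, 22]
GROUP_C = [25, 27, 24, 26, 28, 47, 48]
R_KW_H = 1.885714285714
R_KW_P = 0.389513348711
R_MWU_U = 20.0
R_MWU_P = 0.138790621144
R_DUNN = {("a", "b"): (-1.018649625153, 0.308369335862),
          ("a", "c"): (-1.282853961180, 0.199543244894),
          ("b", "c"): (-0.292770021885, 0.769697943781)}


class TestReferenceAgreement:
    def groups(self):
        return {"a": np.array(GROUP_A, float), "b": np.array(GROUP_B, float),
                "c": np.array(GROUP_C, float)}

    def test_kruskal_wallis_matches_reference(self):
        rep = compare(self.groups())
        assert rep.test == "kruskal-wallis"
        assert rep.statistic == pytest.approx(R_KW_H, abs=1e-8)
        assert rep.p_value == pytest.approx(R_KW_P, abs=1e-8)

    def test_dunn_matches_reference(self):
        df = dunn_test(self.groups())
        for row in df.itertuples():
            z_ref, p_ref = R_DUNN[(row.group1, row.group2)]
            assert row.z == pytest.approx(z_ref, abs=1e-8)
            assert row.p_raw == pytest.approx(p_ref, abs=1e-8)

    def test_mann_whitney_matches_reference(self):
        from scipy import stats as sps
        res = sps.mannwhitneyu(GROUP_A, GROUP_B, alternative="two-sided",
                               method="exact")
        assert res.statistic == pytest.approx(R_MWU_U, abs=1e-8)
        assert res.pvalue == pytest.approx(R_MWU_P, abs=1e-8)

    def test_holm_correction_monotone(self):
        df = dunn_test(self.groups(), p_adjust="holm")
        assert (df["p_corrected"] >= df["p_raw"] - 1e-15).all()


class TestScreen:
    def test_normal_samples_pass(self):
        # two groups each passing Shapiro at alpha = 0.05 has probability
        # 0.95^2 ~ 0.90; allow two binomial SDs below that over 40 draws
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            flags = screen({"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50)})
            hits += flags.normal
        assert hits >= 33

    def test_heavy_tails_fail(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            flags = screen({"a": rng.standard_cauchy(50),
                            "b": rng.normal(0, 1, 50)})
            hits += not flags.normal
        assert hits >= 19  # >= 95% of seeds

    def test_tiny_group_forces_nonparametric(self):
        flags = screen({"a": np.array([1.0, 2.0]), "b": np.random.default_rng(2
                        ).normal(0, 1, 30)})
        assert not flags.normal
        assert "a" in flags.small_groups


class TestCompare:
    def test_null_calibration_nonparametric(self):
        """Type-I error of the Kruskal-Wallis path stays near nominal:
        <= 7% rejections at alpha = 0.05 over 1000 null simulations."""
        from scipy import stats as sps
        rng = np.random.default_rng(3)
        rej = sum(
            sps.kruskal(*(rng.normal(0, 1, 15) for _ in range(3))).pvalue < 0.05
            for _ in range(1000))
        assert rej / 1000 <= 0.07

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(4)
        nonsig = 0
        for _ in range(50):
            g = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
                 "c": rng.normal(0, 1, 20)}
            nonsig += compare(g).p_value >= 0.05
        assert nonsig >= 44  # >= ~94% of seeds (binomial slack at n = 50)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        sig = 0
        for _ in range(30):
            g = {"a": rng.normal(0, 1, 20), "b": rng.normal(3, 1, 20)}
            sig += compare(g).p_value < 0.05
        assert sig == 30

    def test_two_group_paths(self):
        rng = np.random.default_rng(6)
        g = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)}
        rep = compare(g)
        assert rep.test in ("t-test", "mann-whitney-u")
        assert rep.posthoc is None  # post hoc only after an omnibus test

    def test_posthoc_only_beyond_two_groups(self):
        rng = np.random.default_rng(7)
        g = {k: rng.normal(0, 1, 10) for k in "abc"}
        rep = compare(g)
        assert rep.test == "kruskal-wallis"
        assert len(rep.posthoc) == 3

    def test_animal_clustering_warns(self):
        rng = np.random.default_rng(8)
        g = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
        ids = {"a": np.repeat([1, 2], 5), "b": np.repeat([3, 4], 5)}
        rep = compare(g, animal_ids=ids)
        assert any("multi-level" in w for w in rep.warnings)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare({"a": np.arange(5.0)})


class TestDescribe:
    def test_one_to_nine(self):
        d = describe(np.arange(1.0, 10.0))
        assert d.median == 5.0 and d.mean == 5.0
        assert d.q1 == 3.0 and d.q3 == 7.0  # type-7 linear interpolation
        assert (d.whisker_lo, d.whisker_hi) == (1.0, 9.0)

    def test_single_value(self):
        d = describe(np.array([4.2]))
        assert d.median == d.mean == d.q1 == d.q3 == 4.2
        assert d.whisker_lo == d.whisker_hi == 4.2

    def test_outlier_excluded_from_whiskers(self):
        d = describe(np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 100.0]))
        assert d.whisker_hi == 9.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
           st.floats(0.1, 10.0), st.floats(-100.0, 100.0))
    def test_affine_equivariance_of_location_stats(self, xs, a, b):
        v = np.asarray(xs)
        d0 = describe(v)
        d1 = describe(a * v + b)
        assert d1.median == pytest.approx(a * d0.median + b, rel=1e-9, abs=1e-6)
        assert d1.q1 == pytest.approx(a * d0.q1 + b, rel=1e-9, abs=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(12))))
    def test_permutation_invariance(self, perm):
        v = np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8])
        assert describe(v[perm]) == describe(v)


class TestNormalizeToControl:
    def frame(self):
        return pd.DataFrame({
            "experiment_id": ["e1"] * 4 + ["e2"] * 4,
            "condition": ["WT", "WT", "KO", "KO"] * 2,
            "value": [10.0, 10.0, 25.0, 15.0, 20.0, 20.0, 50.0, 30.0],
        })

    def test_division_by_experiment_control_mean(self):
        out = normalize_to_control(self.frame(), "value", "WT")
        assert out.iloc[2] == pytest.approx(2.5)
        assert out.iloc[6] == pytest.approx(2.5)

    def test_control_mean_is_one(self):
        df = self.frame()
        out = normalize_to_control(df, "value", "WT")
        for exp in ("e1", "e2"):
            sel = (df.experiment_id == exp) & (df.condition == "WT")
            assert out[sel].mean() == pytest.approx(1.0)

    def test_missing_control_block_rejected(self):
        df = self.frame()
        df.loc[df.experiment_id == "e2", "condition"] = "KO"
        with pytest.raises(ValueError, match="control"):
            normalize_to_control(df, "value", "WT")
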