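"""Group statistics: normality, ANOVA, SNK, repeated measures, Pearson."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cardiomet import stats, tables
from cardiomet.stats import (
    normality,
    one_way_anova,
    pearson,
    repeated_measures,
    snk_posthoc,
)
from cardiomet.synthio import CohortSpec, gen_cohort


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(500)
            _, p = normality(x)
            rejections += p < 0.05
        assert rejections <= 10

    def test_exponential_samples_usually_rejected(self):
        rejections = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=50)
            _, p = normality(x)
            rejections += p < 0.05
        assert rejections >= 40

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality(np.array([1.0, 2.0, 3.0]))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality(np.full(10, 3.0))


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = {"a": [1, 2, 3.0], "b": [1, 2, 3.0], "c": [1, 2, 3.0]}
        res = one_way_anova(g)
        assert res.statistic == 0.0

    def test_large_shift_detected(self, rng):
        g = {"a": rng.standard_normal(8), "b": rng.standard_normal(8),
             "c": rng.standard_normal(8) + 10.0}
        assert one_way_anova(g).p_value < 0.001

    def test_matches_reference_implementation(self, rng):
        for _ in range(25):
            g = {f"g{i}": rng.normal(rng.uniform(-1, 1), 1.0,
                                     int(rng.integers(3, 12)))
                 for i in range(int(rng.integers(2, 5)))}
            res = one_way_anova(g)
            f_ref, p_ref = sps.f_oneway(*g.values())
            assert res.statistic == pytest.approx(f_ref, abs=1e-10)
            assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_affine_invariance_of_f(self, rng):
        g = {"a": rng.standard_normal(6), "b": rng.standard_normal(6) + 1}
        f1 = one_way_anova(g).statistic
        g2 = {k: 3.5 * np.asarray(v) - 7.0 for k, v in g.items()}
        assert one_way_anova(g2).statistic == pytest.approx(f1, rel=1e-12)

    def test_degenerate_all_identical_flagged(self):
        res = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert math.isnan(res.statistic) and res.flags


class TestSNK:
    def test_identical_groups_no_significant_pairs(self, rng):
        x = rng.standard_normal(8)
        res = snk_posthoc({"a": x, "b": x + 1e-9, "c": x - 1e-9})
        assert not any(res["pairs"].values())

    def test_single_shifted_group_flags_exactly_its_pairs(self, rng):
        g = {"a": rng.standard_normal(8), "b": rng.standard_normal(8),
             "c": rng.standard_normal(8) + 10.0}
        res = snk_posthoc(g)
        sig = {pair for pair, s in res["pairs"].items() if s}
        assert sig == {("a", "c"), ("b", "c")}

    def test_step_down_never_beats_extreme_pair(self, rng):
        # inner pairs cannot be significant when the spanning stretch is not
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = {k: r.normal(m, 1, 8) for k, m in
                 zip("abc", r.uniform(0, 1.5, 3))}
            res = snk_posthoc(g)
            means = {k: np.mean(v) for k, v in g.items()}
            names = sorted(g, key=means.get)
            extreme = (names[0], names[2])
            if not res["pairs"][extreme]:
                assert not any(res["pairs"].values())

    def test_harmonic_mean_flagged_for_unequal_n(self, rng):
        g = {"a": rng.standard_normal(5), "b": rng.standard_normal(9)}
        res = snk_posthoc(g)
        assert any("harmonic" in f for f in res["flags"])

    def test_gate_on_omnibus_when_requested(self, rng):
        x = rng.standard_normal(6)
        res = snk_posthoc({"a": x, "b": x + 0.01}, require_significant=True)
        assert not any(res["pairs"].values())


class TestRepeatedMeasures:
    def test_no_time_change_gives_near_zero_f(self, rng):
        b = {g: rng.standard_normal(8) for g in "abc"}
        a = {g: v.copy() for g, v in b.items()}
        res = repeated_measures(b, a)
        assert res["time"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_single_group_time_f_equals_paired_t_squared(self, rng):
        before = rng.normal(100, 10, 12)
        after = before + rng.normal(3, 4, 12)
        res = repeated_measures({"g": before}, {"g": after})
        t, p = sps.ttest_rel(after, before)
        assert res["time"].statistic == pytest.approx(t ** 2, abs=1e-8)
        assert res["time"].p_value == pytest.approx(p, abs=1e-10)

    def test_group_specific_shift_yields_interaction(self):
        detections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            before = {g: r.normal(100, 5, 8) for g in ("x", "y")}
            after = {"x": before["x"] + r.normal(0, 2, 8),
                     "y": before["y"] + 20 + r.normal(0, 2, 8)}
            res = repeated_measures(before, after)
            detections += res["interaction"].p_value < 0.05
        assert detections >= 19

    def test_missing_pairs_dropped_with_warning(self, rng):
        b = {"g": np.array([1.0, 2.0, 3.0, np.nan, 5.0])}
        a = {"g": np.array([2.0, 3.0, 4.0, 5.0, 6.0])}
        with pytest.warns(UserWarning, match="missing"):
            res = repeated_measures(b, a)
        assert res["time"].df[1] == 3  # 4 complete pairs - 1 group

    def test_matches_mixed_anova_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        b = {g: rng.normal(m, 2, 8) for g, m in [("x", 10.0), ("y", 12.0)]}
        a = {g: v + rng.normal(1.5, 1, 8) for g, v in b.items()}
        res = repeated_measures(b, a)
        rows = []
        sid = 0
        for g in b:
            for i in range(8):
                rows.append((f"s{sid}", g, "before", b[g][i]))
                rows.append((f"s{sid}", g, "after", a[g][i]))
                sid += 1
        df = pd.DataFrame(rows, columns=["subject", "group", "time", "y"])
        ref = pingouin.mixed_anova(df, dv="y", within="time", between="group",
                                   subject="subject")
        ref = ref.set_index("Source")["F"]
        assert res["group"].statistic == pytest.approx(ref["group"], rel=1e-6)
        assert res["time"].statistic == pytest.approx(ref["time"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            ref["Interaction"], rel=1e-6)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_series_low_correlation(self):
        small = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            r, _ = pearson(rng.standard_normal(100), rng.standard_normal(100))
            small += abs(r) < 0.3
        assert small >= 57

    def test_symmetry_and_bounds(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r_xy, _ = pearson(x, y)
        r_yx, _ = pearson(y, x)
        assert r_xy == pytest.approx(r_yx)
        assert -1.0 <= r_xy <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_cohort_fat_fibrosis_correlation_recovered(self):
        # model-implied pooled r over three groups with within-group rho=0.89
        rho = 0.89
        wat = tables.ENDPOINTS["wat"]
        col = tables.ENDPOINTS["lv_vv_collagen"]
        sd = {g: (wat[g][1] * math.sqrt(8), col[g][1] * math.sqrt(8))
              for g in tables.GROUPS}
        mw = np.mean([wat[g][0] for g in tables.GROUPS])
        mc = np.mean([col[g][0] for g in tables.GROUPS])
        cov = np.mean([rho * sd[g][0] * sd[g][1] for g in tables.GROUPS]) + \
            np.mean([(wat[g][0] - mw) * (col[g][0] - mc) for g in tables.GROUPS])
        vw = np.mean([sd[g][0] ** 2 for g in tables.GROUPS]) + \
            np.mean([(wat[g][0] - mw) ** 2 for g in tables.GROUPS])
        vc = np.mean([sd[g][1] ** 2 for g in tables.GROUPS]) + \
            np.mean([(col[g][0] - mc) ** 2 for g in tables.GROUPS])
        implied = cov / math.sqrt(vw * vc)

        rs = []
        for seed in range(15):
            animals = gen_cohort(CohortSpec(n_per_group=8, seed=seed))
            x = [a.endpoints["wat"] for a in animals]
            y = [a.endpoints["lv_vv_collagen"] for a in animals]
            rs.append(pearson(np.array(x), np.array(y))[0])
        assert np.median(rs) == pytest.approx(implied, abs=0.1)
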