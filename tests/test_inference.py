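"""Exact oracles, Monte-Carlo power and calibration spot-checks for the
non-parametric test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hrvmefa.inference import (
    SensitivityConfig,
    ats_longitudinal,
    ba_density_test,
    epoch_pair_trends,
    fdr_adjust,
    jt_test,
    ks_bootstrap_test,
    sensitivity_scores,
    sexage_screen,
    stwrs_test,
    wsr_test,
)


def _long_panel(rng, n=15, T=9, shift=0.0, trend=0.0, interaction=0.0):
    rows = []
    for g, gname in ((0, "A"), (1, "B")):
        for k in range(n):
            base = rng.normal()
            for t in range(1, T + 1):
                v = (base + rng.normal() + shift * g + trend * t
                     + interaction * g * t)
                rows.append({"subject": f"{gname}{k}", "group": gname,
                             "epoch": t, "val": v})
    return pd.DataFrame(rows)


class TestATS:
    def test_group_shift_detected_without_epoch_effect(self):
        rng = np.random.default_rng(0)
        r = ats_longitudinal(_long_panel(rng, shift=2.0), "val")
        assert r.group_effect.p_value < 1e-3
        assert r.epoch_effect.p_value > 0.05

    def test_shared_trend_detected_without_interaction(self):
        rng = np.random.default_rng(1)
        r = ats_longitudinal(_long_panel(rng, trend=0.5), "val")
        assert r.epoch_effect.p_value < 1e-3
        assert r.interaction.p_value > 0.05

    def test_interaction_detected(self):
        rng = np.random.default_rng(2)
        r = ats_longitudinal(_long_panel(rng, interaction=0.4), "val")
        assert r.interaction.p_value < 1e-3

    def test_single_group_epoch_effect(self):
        rng = np.random.default_rng(3)
        df = _long_panel(rng, trend=0.5)
        r = ats_longitudinal(df, "val", groups=False)
        assert r.group_effect is None and r.interaction is None
        assert r.epoch_effect.p_value < 1e-3

    def test_small_group_rejected(self):
        rng = np.random.default_rng(4)
        df = _long_panel(rng, n=3)
        df = df[~((df["group"] == "A") & (df["subject"] != "A0"))]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            ats_longitudinal(df, "val")

    def test_missing_epoch_rejected(self):
        rng = np.random.default_rng(5)
        df = _long_panel(rng)
        df = df[~((df["subject"] == "A0") & (df["epoch"] == 4))]
        with pytest.raises(ValueError, match="missing"):
            ats_longitudinal(df, "val")


class TestBA:
    def test_identical_multisets_give_zero_statistic(self):
        x = np.arange(10.0)
        r = ba_density_test(x, x[::-1].copy(), 300, seed=0)
        assert r.statistic == pytest.approx(0.0, abs=1e-20)
        assert r.p_value == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(6)
        r = ba_density_test(rng.normal(0, 1, 15), rng.normal(3, 1, 15), 999, seed=1)
        assert r.p_value <= 0.01

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert ba_density_test(x, y, 200, 5).p_value == ba_density_test(x, y, 200, 5).p_value

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ba_density_test([1, 2, 3], [4, 5, 6, 7, 8])


class TestJT:
    def test_exact_enumeration_oracle(self):
        # full enumeration of the 6 assignments of {1,2,3,4} into 2+2
        r = jt_test([[1, 2], [3, 4]], alternative="increasing")
        assert r.exact
        assert r.p_value == pytest.approx(1 / 6)

    def test_two_groups_reduce_to_mann_whitney_count(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        x, y = rng.normal(size=8), rng.normal(size=9)
        r = jt_test([x, y], 100, seed=0)
        u = mannwhitneyu(y, x, alternative="two-sided").statistic
        assert r.statistic == pytest.approx(u)

    def test_monte_carlo_matches_exact_in_the_limit(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 3.0, 6.0]
        exact = jt_test([x, y], alternative="increasing")
        mc = jt_test([x, y], 20000, seed=3, alternative="increasing",
                     exact_limit=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jt_test([[1.0, 2.0], []])


class TestKS:
    def test_identical_samples(self):
        x = np.arange(10.0)
        r = ks_bootstrap_test(x, x.copy(), 200, seed=0)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_disjoint_supports_statistic_is_one(self):
        r = ks_bootstrap_test(np.arange(10.0), np.arange(100.0, 110.0), 100, seed=0)
        assert r.statistic == 1.0
        assert r.p_value <= 0.05


class TestStWRS:
    def test_label_swap_symmetric_under_enumeration(self):
        r = stwrs_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.exact
        assert r.p_value >= 0.99

    def test_large_shift_detected(self):
        rng = np.random.default_rng(9)
        r = stwrs_test(rng.normal(0, 1, 15), rng.normal(3, 1, 15), 999, seed=0)
        assert r.p_value <= 0.01

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            stwrs_test([5.0] * 6, [5.0] * 6)


class TestWSR:
    def test_exact_sign_flip_oracle(self):
        # differences [1, 2, 3]: only the all-positive pattern reaches W+=6
        r = wsr_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], alternative="greater")
        assert r.exact
        assert r.p_value == pytest.approx(1 / 8)

    def test_no_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            wsr_test([1.0, 2.0], [1.0, 2.0])

    def test_null_monte_carlo_reproducible(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        b = a + rng.normal(size=30)
        r1 = wsr_test(a, b, 500, seed=4)
        r2 = wsr_test(a, b, 500, seed=4)
        assert r1.p_value == r2.p_value


class TestFDR:
    def test_step_up_hand_oracle(self):
        adj = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])

    def test_false_discovery_proportion_controlled(self):
        # 8 independent null hypotheses: expected FDP at level 0.05 stays
        # below the nominal level
        rng = np.random.default_rng(11)
        fdp = []
        for _ in range(500):
            p = rng.uniform(size=8)
            rejected = fdr_adjust(p) <= 0.05
            fdp.append(rejected.mean())
        assert np.mean(fdp) <= 0.05


class TestSexAgeScreen:
    @staticmethod
    def _draw(rng, n=30, effect=0.0):
        sex = (rng.random(n) > 0.4).astype(int)
        age = rng.uniform(18, 40, n)
        y = rng.normal(size=n) + effect * sex
        return y, sex, age

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(12)
        any_sig = 0
        for _ in range(100):
            y, sex, age = self._draw(rng)
            res = sexage_screen(y, sex, age)
            any_sig += any(r.p_value <= 0.05 for r in res.values())
        # familywise over 3 terms; Bonferroni-level bound
        assert any_sig <= 25

    def test_strong_sex_effect_detected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(50):
            y, sex, age = self._draw(rng, effect=10.0)
            res = sexage_screen(y, sex, age)
            hits += res["sex"].p_value <= 0.05
        assert hits >= 45

    def test_single_sex_drops_terms(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=20)
        age = rng.uniform(18, 40, 20)
        with pytest.warns(UserWarning, match="single-sex"):
            res = sexage_screen(y, np.zeros(20, int), age)
        assert set(res) == {"age"}


class TestEpochPairTrends:
    @staticmethod
    def _ws_table(rng, n=30, profile=None, noise=1.0):
        profile = profile if profile is not None else np.zeros(9)
        rows = []
        for k in range(n):
            for t in range(1, 10):
                rows.append({"subject": f"s{k}", "group": "g", "epoch": t,
                             "ind": profile[t - 1] + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_u_shaped_profile_detected(self):
        rng = np.random.default_rng(15)
        profile = np.array([80, 80, 60, 40, 20, 10, 5, 40, 70], float)
        tr = epoch_pair_trends(self._ws_table(rng, profile=profile, noise=5.0),
                               "ind", n_permutations=400, seed=0)
        sig = tr[tr["significant"]]
        for pair in ["2-3", "3-4", "4-5", "5-6", "7-8", "8-9"]:
            assert (sig["pair"] == pair).any(), f"pair {pair} not flagged"
        decr = tr[(tr["pair"] == "4-5") & (tr["method"] == "WSR")]
        assert decr["direction"].iloc[0] == "decrease"

    def test_flat_profile_rarely_flagged(self):
        rng = np.random.default_rng(16)
        n_many = 0
        for _ in range(10):
            tr = epoch_pair_trends(self._ws_table(rng), "ind",
                                   n_permutations=300, seed=1)
            n_many += tr.groupby("method")["significant"].sum().max() > 1
        assert n_many <= 1

    def test_missing_epoch_rejected(self):
        rng = np.random.default_rng(17)
        t = self._ws_table(rng)
        with pytest.raises(ValueError, match="epochs"):
            epoch_pair_trends(t[t["epoch"] != 5], "ind")


class TestSensitivity:
    def test_all_significant_is_strong(self):
        battery = {"X-WS-Ind": {
            "rest-stand": {"ATS": True, "WSR": True, "bootstrap-CI": True},
            "exercise-fraction": {f"{t}-{t+1}": {"ATS": True, "WSR": True}
                                  for t in range(2, 9)},
            "sports-specialties": {"overall": {"ATS-group": True},
                                   "epochs": {"ep1": {"BA": True, "JT": True}}},
        }}
        rep = sensitivity_scores(battery)
        lv = rep.levels["X-WS-Ind"]
        assert lv["rest-stand"] == "strong"
        assert lv["exercise-fraction"] == "strong"
        assert lv["sports-specialties"] == "strong"

    def test_zero_significant_is_none(self):
        battery = {"X": {
            "rest-stand": {"ATS": False, "WSR": False},
            "exercise-fraction": {"2-3": {"ATS": False, "WSR": False}},
            "sports-specialties": {"overall": {"ATS-group": False},
                                   "epochs": {"ep1": {"BA": False}}},
        }}
        lv = sensitivity_scores(battery).levels["X"]
        assert set(lv.values()) == {"none"}

    def test_two_of_four_is_medium(self):
        battery = {"X": {"rest-stand": {"a": True, "b": True, "c": False, "d": False}}}
        assert sensitivity_scores(battery).levels["X"]["rest-stand"] == "medium"

    def test_missing_aspect_not_evaluable(self):
        rep = sensitivity_scores({"X": {"rest-stand": {"a": True}}})
        assert rep.levels["X"]["exercise-fraction"] == "not-evaluable"
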