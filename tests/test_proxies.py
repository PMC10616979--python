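"""Closed-form and property tests for the 12 ANS proxies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvmefa.proxies import (
    ARSpectrum,
    RRSeries,
    band_powers,
    compute_proxies,
    compute_proxy_panel,
    detrend_rr,
    fit_ar_spectrum,
    prsa,
    quantize_series,
    regularity_ro,
    symbolic_p0v,
    symbolic_pattern_shares,
    time_domain,
)


class TestDetrend:
    def test_exact_line_gives_zero_residuals(self):
        idx = np.arange(50)
        out = detrend_rr(800.0 + 1.5 * idx)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_constant_series_gives_zero_residuals(self):
        assert np.allclose(detrend_rr(np.full(30, 950.0)), 0.0, atol=1e-9)

    def test_trendless_noise_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 20.0, 400) + 900.0
        out = detrend_rr(x)
        # least-squares oracle: the fitted slope must be within 2 s.e. of 0
        idx = np.arange(x.size)
        slope = np.polyfit(idx, x, 1)[0]
        resid = x - np.polyval(np.polyfit(idx, x, 1), idx)
        se = np.sqrt(resid.var(ddof=2) / ((idx - idx.mean()) ** 2).sum())
        assert abs(slope) < 2 * se
        assert np.allclose(out + x.mean(), x, atol=3 * se * x.size)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detrend_rr([800.0, 810.0])


class TestTimeDomain:
    @pytest.mark.parametrize(
        "rr, expect",
        [
            ([1000.0] * 8, (60.0, 0.0, 0.0)),
            ([900.0, 1100.0], (60.0, 100.0, 200.0)),
        ],
    )
    def test_closed_forms(self, rr, expect):
        hr, rms, rmssd = time_domain(rr)
        assert hr == pytest.approx(expect[0])
        assert rms == pytest.approx(expect[1])
        assert rmssd == pytest.approx(expect[2])

    def test_rmssd_hand_computation(self):
        # diffs are +-10 -> RMSSD = 10
        _, _, rmssd = time_domain([800.0, 810.0, 800.0, 810.0])
        assert rmssd == pytest.approx(10.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = 900.0 + rng.normal(0, 25, 300)
        h0, rms0, rd0 = time_domain(x)
        h1, rms1, rd1 = time_domain(x + 150.0)
        assert rms1 == pytest.approx(rms0)
        assert rd1 == pytest.approx(rd0)
        assert h1 != pytest.approx(h0)


class TestARSpectrum:
    def test_white_noise_total_power_matches_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 30, 2048)
        sp = fit_ar_spectrum(x, 1000.0)
        assert sp.total_power == pytest.approx(x.var(), rel=0.10)
        sp.validate(tol=0.01)  # component powers sum to total power

    def test_known_pole_frequency_recovered(self):
        # AR(2) with spectral peak at 0.25 cycles/beat == 0.25 Hz at RR 1 s
        r, th = 0.95, 2 * np.pi * 0.25
        a1, a2 = 2 * r * np.cos(th), -(r**2)
        rng = np.random.default_rng(2)
        x = np.zeros(4096)
        eps = rng.normal(0, 1, 4096)
        for t in range(2, 4096):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + eps[t]
        sp = fit_ar_spectrum(x[500:], 1000.0)
        f_dom = max(sp.components, key=lambda c: c[1])[0]
        assert abs(f_dom - 0.25) < 0.03

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            fit_ar_spectrum(np.zeros(512), 1000.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fit_ar_spectrum(np.random.default_rng(0).normal(size=40), 1000.0)


def _spec(components):
    return ARSpectrum(
        order=2, coefficients=np.zeros(2), innovation_variance=1.0,
        components=components, total_power=sum(p for _, p in components),
        mean_rr_ms=1000.0,
    )


class TestBandPowers:
    def test_single_hf_component(self):
        tp, lfa, hfa, lfnu, hfnu = band_powers(_spec([(0.25, 400.0)]))
        assert (lfa, hfa) == (0.0, 400.0)
        assert hfnu == pytest.approx(100.0)

    def test_lf_hf_ratio(self):
        tp, lfa, hfa, lfnu, hfnu = band_powers(_spec([(0.10, 300.0), (0.25, 100.0)]))
        assert lfnu == pytest.approx(75.0)
        assert hfnu == pytest.approx(25.0)

    def test_vlf_component_stays_in_tp_only(self):
        tp, lfa, hfa, lfnu, hfnu = band_powers(_spec([(0.01, 500.0), (0.10, 500.0)]))
        assert lfa == pytest.approx(500.0)
        assert lfnu == pytest.approx(100.0)
        assert tp == pytest.approx(1000.0)

    def test_empty_bands_give_nan(self):
        tp, lfa, hfa, lfnu, hfnu = band_powers(_spec([(0.01, 500.0)]))
        assert lfa == hfa == 0.0
        assert np.isnan(lfnu) and np.isnan(hfnu)

    @given(st.lists(
        st.tuples(st.floats(0.001, 0.6), st.floats(0.0, 1e4)),
        min_size=1, max_size=8,
    ))
    @settings(max_examples=60, derandomize=True)
    def test_band_assignment_is_partition(self, comps):
        tp, lfa, hfa, lfnu, hfnu = band_powers(_spec(comps))
        in_lf = sum(p for f, p in comps if 0.03 < f < 0.15)
        in_hf = sum(p for f, p in comps if 0.15 <= f <= 0.40)
        assert lfa == pytest.approx(in_lf)
        assert hfa == pytest.approx(in_hf)
        assert lfa + hfa <= tp + 1e-9
        if not np.isnan(lfnu):
            assert lfnu + hfnu <= 100.0 + 1e-9


class TestPRSA:
    def test_constant_series_has_no_anchors(self):
        assert np.isnan(prsa(np.full(50, 900.0), "acceleration", window_L=5))

    def test_monotone_wrong_direction_has_no_anchors(self):
        x = 900 + 0.5 * np.arange(60)  # strictly increasing
        assert np.isnan(prsa(x, "acceleration", window_L=5))

    def test_alternation_matches_enumeration_oracle(self):
        rr = np.array([1000, 990, 1000, 990, 1000, 990, 1000, 990, 1000], float)
        L = 2
        # oracle: enumerate admissible anchors and average windows by hand
        anchors = [
            i for i in range(1, len(rr))
            if rr[i] < rr[i - 1] and abs(rr[i] - rr[i - 1]) <= 0.05 * rr[i - 1]
            and i - L >= 0 and i + L <= len(rr) - 1
        ]
        X = np.mean([rr[i - L: i + L + 1] for i in anchors], axis=0)
        expect = (X[L] + X[L + 1] - X[L - 1] - X[L - 2]) / 4.0
        assert prsa(rr, "acceleration", window_L=L) == pytest.approx(expect)

    def test_time_reversal_swaps_anchor_roles(self):
        # Reversing time turns every RR decrease into an increase seen from
        # the other side: acceleration anchors map onto deceleration anchors
        # of the reversed series and the averaged windows mirror, giving
        # AC(x) = -DC(reversed x) exactly.  Strictly increasing ramps at
        # both ends keep the boundary regions anchor-free so the admissible
        # anchor sets map one-to-one.
        rng = np.random.default_rng(5)
        L = 8
        middle = 900 + rng.normal(0, 15, 300)
        ramp = 700 + 5.0 * np.arange(L + 4)
        x = np.concatenate([ramp, middle, ramp])
        ac = prsa(x, "acceleration", window_L=L, max_rel_change=np.inf)
        dc_rev = prsa(x[::-1], "deceleration", window_L=L, max_rel_change=np.inf)
        assert ac == pytest.approx(-dc_rev, abs=1e-9)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            prsa(np.arange(10.0) + 800, "acceleration", window_L=10)


class TestSymbolic:
    def test_constant_series_p0v_100(self):
        assert symbolic_p0v([800.0] * 10) == 100.0

    def test_uniform_ramp_p0v_0(self):
        assert symbolic_p0v([700, 760, 820, 880, 940, 1000]) == 0.0

    def test_two_level_half(self):
        assert symbolic_p0v([800, 800, 800, 900, 900, 900], n_levels=2) == 50.0

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(7)
        shares = symbolic_pattern_shares(rng.uniform(700, 1100, 500))
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_edge_ties_go_to_lower_bin(self):
        # 850 sits exactly on the 3-level edge between bins 0 and 1
        sym = quantize_series([800.0, 850.0, 950.0], n_levels=3)
        assert sym.tolist() == [0, 0, 2]

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(700, 1100, 400)
        assert symbolic_p0v(x) == symbolic_p0v(x + 123.0)
        assert regularity_ro(x) == pytest.approx(regularity_ro(x + 123.0))


class TestRegularity:
    def test_constant_series_is_fully_regular(self):
        assert regularity_ro([900.0] * 200) == 1.0

    def test_white_noise_is_irregular(self):
        rng = np.random.default_rng(11)
        vals = [regularity_ro(rng.uniform(800, 1000, 1000)) for _ in range(50)]
        assert np.mean(vals) < 0.2

    def test_period_two_alternation_is_regular(self):
        assert regularity_ro([800.0, 900.0] * 100) > 0.8


class TestPanel:
    def test_study_panel_shape(self, study_panel):
        assert study_panel.shape == (270, 15)
        assert study_panel.groupby("subject")["epoch"].nunique().eq(9).all()

    def test_hf_dominant_series_has_high_hfnu(self):
        from hrvmefa.synthetic import EpochProfile, generate_rr_epoch

        prof = EpochProfile(epoch_index=1, mean_rr=900, lf_power=20,
                            hf_power=900, n_beats=1024, noise_sd=1.0)
        s = generate_rr_epoch(prof, seed=4)
        row = compute_proxies(s)
        assert row["RR_HFnu"] > row["RR_LFnu"]

    def test_incomplete_subject_named_in_error(self, study_panel):
        series = [
            RRSeries("solo", "g", e, 900 + 20 * np.random.default_rng(e).normal(size=200))
            for e in range(1, 9)  # only 8 epochs
        ]
        with pytest.raises(ValueError, match="solo"):
            compute_proxy_panel(series)
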