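"""Oracles and properties for the two-level factor analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hrvmefa.datasets import (
    BS_REFERENCE_SUMMARY,
    WS_REFERENCE_SUMMARY,
    bs_reference_loadings,
    ws_reference_loadings,
)
from hrvmefa.mefa import (
    MefaConfig,
    choose_n_factors,
    decompose_panel,
    factor_scores,
    fit_mefa,
    kmo,
    label_factors,
    pkde_transform,
    principal_factor,
    summarize_solution,
    varimax_rotate,
)
from hrvmefa.resampling import tucker_congruence
from hrvmefa.synthetic import default_panel_spec, generate_proxy_panel


class TestDecompose:
    def test_centering_identity(self, latent_panel):
        _, panel = latent_panel
        _, xt, _ = decompose_panel(panel)
        vars_ = panel.columns[3:]
        per_subject = xt.groupby("subject")[list(vars_)].mean().to_numpy()
        assert np.abs(per_subject).max() < 1e-10

    def test_identical_epochs_raise_ws_error(self):
        rows = []
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 2))
        for i in range(4):
            for ep in (1, 2, 3):
                rows.append({"subject": f"s{i}", "group": "g", "epoch": ep,
                             "A": vals[i, 0], "B": vals[i, 1]})
        panel = pd.DataFrame(rows)
        with pytest.raises(ValueError, match="WS"):
            decompose_panel(panel, variables=["A", "B"])

    def test_pooled_ws_equals_textbook_two_step(self, latent_panel):
        # brute-force oracle: pool within-subject covariances, then normalize
        _, panel = latent_panel
        vars_ = list(panel.columns[3:])
        _, xt, pair = decompose_panel(panel)
        X = panel.sort_values(["subject", "epoch"])
        S = np.zeros((len(vars_), len(vars_)))
        n_rows = 0
        for _, g in X.groupby("subject"):
            d = g[vars_].to_numpy() - g[vars_].to_numpy().mean(axis=0)
            S += d.T @ d
            n_rows += len(g)
        S /= n_rows
        dd = np.sqrt(np.diag(S))
        R_oracle = S / np.outer(dd, dd)
        assert np.abs(pair.R_W - R_oracle).max() < 1e-10


class TestKMO:
    def test_equicorrelated_closed_form(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        # partials of 3 equicorrelated variables are rho/(1+rho) = 1/3
        expect = (6 * 0.25) / (6 * 0.25 + 6 * (1 / 3) ** 2)
        assert kmo(R) == pytest.approx(expect)
        assert kmo(R) == pytest.approx(0.6923, abs=1e-4)

    def test_identity_matrix_errors(self):
        with pytest.raises(ValueError, match="no correlation structure"):
            kmo(np.eye(4))

    def test_result_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = rng.normal(size=(30, 6))
            R = np.corrcoef(A, rowvar=False)
            assert 0.0 <= kmo(R) <= 1.0


class TestPrincipalFactor:
    def test_exact_one_factor_recovery(self):
        lam = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        L, h, heywood = principal_factor(R, 1, tol=1e-9)
        assert not heywood
        assert np.allclose(np.abs(L.ravel()), lam, atol=1e-4)

    def test_q_zero_rejected(self):
        with pytest.raises(ValueError):
            principal_factor(np.eye(3), 0)

    def test_constructed_heywood_flagged(self):
        # classic Heywood pattern: r12 = r13 = 0.9 but r23 = 0.3 forces the
        # first variable's communality past 1
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.3], [0.9, 0.3, 1.0]])
        _, h, heywood = principal_factor(R, 1)
        assert heywood
        assert h.max() > 1.0


class TestVarimax:
    def test_single_factor_unchanged(self):
        L = np.array([[0.8], [0.6], [-0.2]])
        assert np.array_equal(varimax_rotate(L), L)

    def test_row_ssq_preserved(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(10, 3)) * 0.4
        rot = varimax_rotate(L)
        assert np.allclose((rot**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-10)

    def test_recovers_simple_structure_after_45_degrees(self):
        simple = np.zeros((6, 2))
        simple[:3, 0] = [0.8, 0.7, 0.9]
        simple[3:, 1] = [0.75, 0.85, 0.65]
        th = np.pi / 4
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = varimax_rotate(simple @ Q)
        # up to column order/sign, already enforced by the convention
        assert np.allclose(np.sort(np.abs(rot).ravel()),
                           np.sort(np.abs(simple).ravel()), atol=1e-6)


class TestChooseFactors:
    def test_exact_two_factor_structure(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.85
        lam[4:, 1] = 0.8
        R = lam @ lam.T + np.diag(1 - (lam**2).sum(axis=1))
        q, rat = choose_n_factors(R)
        assert q == 2
        assert rat["q_eigen_rule"] >= 2

    def test_no_structure_errors(self):
        rng = np.random.default_rng(3)
        R = np.corrcoef(rng.normal(size=(2000, 8)), rowvar=False)
        with pytest.raises(ValueError, match="eigen"):
            choose_n_factors(R)

    def test_generator_ground_truth_selected(self):
        hits = 0
        for seed in range(5):
            panel = generate_proxy_panel(default_panel_spec(seed=300 + seed))
            _, _, pair = decompose_panel(panel)
            qb, _ = choose_n_factors(pair.R_B)
            qw, _ = choose_n_factors(pair.R_W)
            hits += (qb, qw) == (2, 3)
        assert hits >= 4


class TestFactorScores:
    def test_noiseless_one_factor_scores_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=400)
        lam = np.array([[0.9], [0.8], [0.7]])
        X = f[:, None] * lam.ravel()
        Z = (X - X.mean(0)) / X.std(0)
        # model-implied correlation matrix (the sample one is rank-1)
        R = lam @ lam.T + np.diag(1.0 - (lam**2).sum(axis=1))
        s = factor_scores(Z, lam, R).ravel()
        assert abs(stats.pearsonr(s, f)[0]) > 0.9999

    def test_zero_row_gives_zero_score(self):
        lam = np.array([[0.8], [0.6]])
        R = np.eye(2)
        s = factor_scores(np.array([[0.0, 0.0], [1.0, 1.0]]), lam, R)
        assert np.allclose(s[0], 0.0)

    def test_uncorrelated_factors_give_uncorrelated_scores(self):
        rng = np.random.default_rng(5)
        n = 500
        f = rng.normal(size=(n, 2))
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.85
        lam[3:, 1] = 0.85
        X = f @ lam.T + rng.normal(size=(n, 6)) * np.sqrt(1 - 0.85**2)
        Z = (X - X.mean(0)) / X.std(0)
        R = np.corrcoef(X, rowvar=False)
        s = factor_scores(Z, lam, R)
        assert abs(np.corrcoef(s, rowvar=False)[0, 1]) < 0.1


class TestPKDE:
    def test_median_maps_near_50(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=301)
        out = pkde_transform(x, eval_at=[np.median(x)])
        assert out[0] == pytest.approx(50.0, abs=2.0)

    def test_far_below_sample_maps_below_1(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        out = pkde_transform(x, eval_at=[x.min() - 10.0])
        assert out[0] < 1.0

    def test_strict_monotonicity_and_rank_preservation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = pkde_transform(x)
        assert stats.spearmanr(x, y)[0] == pytest.approx(1.0)
        grid = np.linspace(x.min(), x.max(), 50)
        g = pkde_transform(x, eval_at=grid)
        assert np.all(np.diff(g) > 0)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            pkde_transform(np.ones(50))

    def test_range_is_0_100(self):
        rng = np.random.default_rng(9)
        y = pkde_transform(rng.normal(size=500))
        assert y.min() >= 0.0 and y.max() <= 100.0


class TestSummaries:
    def test_single_marker_column(self):
        L = np.zeros((12, 1))
        L[0, 0] = 1.0
        s = summarize_solution(L)
        assert s["variance_pct"][0] == pytest.approx(100.0 / 12)
        assert s["communality_share_pct"][0] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "loadings, ref",
        [
            (bs_reference_loadings(), BS_REFERENCE_SUMMARY),
            (ws_reference_loadings(), WS_REFERENCE_SUMMARY),
        ],
        ids=["between", "within"],
    )
    def test_reference_tables_reproduced(self, loadings, ref):
        s = summarize_solution(loadings.to_numpy())
        assert np.allclose(s["variance_pct"], ref["variance_pct"], atol=0.05)
        assert np.allclose(s["cumulative_pct"], ref["cumulative_pct"], atol=0.05)
        assert np.allclose(
            s["communality_share_pct"], ref["communality_share_pct"], atol=0.05
        )
        assert s["total_communality"] == pytest.approx(
            ref["total_communality"], abs=0.01
        )

    def test_rotation_preserves_total_communality(self):
        rng = np.random.default_rng(10)
        L = rng.normal(size=(12, 3)) * 0.4
        before = summarize_solution(L)["total_communality"]
        after = summarize_solution(varimax_rotate(L))["total_communality"]
        assert after == pytest.approx(before, abs=1e-10)


class TestLabels:
    def test_reference_bs_labels(self):
        labels, lmap = label_factors(
            bs_reference_loadings().to_numpy(), "BS",
            tuple(bs_reference_loadings().index),
        )
        assert labels == ("Amplitude", "Frequency")
        assert lmap == {"BS factor 1": "AMP-BS-Ind", "BS factor 2": "FRE-BS-Ind"}

    def test_reference_ws_labels(self):
        labels, lmap = label_factors(
            ws_reference_loadings().to_numpy(), "WS",
            tuple(ws_reference_loadings().index),
        )
        assert labels == ("Amplitude", "Signal Self-Similarity", "Oscillatory")
        assert list(lmap.values()) == ["AMP-WS-Ind", "SSS-WS-Ind", "OSC-WS-Ind"]

    def test_zero_loadings_generic_with_warning(self):
        with pytest.warns(UserWarning, match="generic"):
            labels, _ = label_factors(np.zeros((12, 2)), "BS")
        assert labels == ("Factor 1", "Factor 2")


class TestEndToEnd:
    def test_parameter_recovery_median_congruence(self):
        worst = []
        for seed in range(10):
            spec = default_panel_spec(seed=500 + seed)
            res = fit_mefa(generate_proxy_panel(spec), q_b=2, q_w=3)
            cb = np.abs(tucker_congruence(spec.bs_loadings, res.bs_solution.loadings))
            cw = np.abs(tucker_congruence(spec.ws_loadings, res.ws_solution.loadings))
            worst.append(min(cb.max(axis=1).min(), cw.max(axis=1).min()))
        assert np.median(worst) > 0.95

    def test_indicators_within_bounds_and_rank_preserving(self, latent_panel):
        _, panel = latent_panel
        res = fit_mefa(panel)
        bs = res.indicators.bs_scores
        for k, col in enumerate(bs.columns[2:]):
            assert bs[col].between(0, 100).all()
            rho = stats.spearmanr(bs[col], res.bs_raw_scores[:, k])[0]
            assert rho == pytest.approx(1.0)


def test_toy_panel_hand_correlation_oracle():
    """Tiny panel whose BS/WS correlations are computed by the raw Pearson
    formula (sum of cross-products), independent of the implementation."""
    vals = {
        ("s1", 1): (1.0, 10.0), ("s1", 2): (3.0, 14.0),
        ("s2", 1): (2.0, 11.0), ("s2", 2): (8.0, 15.0),
        ("s3", 1): (0.0, 9.0), ("s3", 2): (1.0, 10.0),
    }
    rows = [
        {"subject": s, "group": "g", "epoch": e, "A": a, "B": b}
        for (s, e), (a, b) in vals.items()
    ]
    panel = pd.DataFrame(rows)
    _, _, pair = decompose_panel(panel, variables=["A", "B"])

    def pearson(u, v):
        u = np.asarray(u) - np.mean(u)
        v = np.asarray(v) - np.mean(v)
        return float((u @ v) / np.sqrt((u @ u) * (v @ v)))

    a_bar = [2.0, 5.0, 0.5]            # per-subject means of A
    b_bar = [12.0, 13.0, 9.5]
    a_cent = [-1, 1, -3, 3, -0.5, 0.5]  # subject-centered values
    b_cent = [-2, 2, -2, 2, -0.5, 0.5]
    assert pair.R_B[0, 1] == pytest.approx(pearson(a_bar, b_bar))
    assert pair.R_W[0, 1] == pytest.approx(pearson(a_cent, b_cent))
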