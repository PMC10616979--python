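"""Non-parametric test battery for group, epoch and interaction effects.

The battery mirrors a rank/permutation testing strategy for small,
non-normal repeated-measures samples:

* :func:`ats_longitudinal` -- the anova-type statistic (ATS) for factorial
  longitudinal designs (one whole-plot group factor, one repeated epoch
  factor), using rank-based relative treatment effects and the Box
  approximation for degrees of freedom;
* two-sample distribution comparisons at a fixed epoch or on subject-level
  scores: Bowman-Azzalini kernel-density permutation test
  (:func:`ba_density_test`), Jonckheere-Terpstra permutation test for
  ordered alternatives (:func:`jt_test`), a bootstrap Kolmogorov-Smirnov
  test with resampling from the pooled sample (:func:`ks_bootstrap_test`),
  and a studentized (Brunner-Munzel type) Wilcoxon rank-sum permutation
  test robust to unequal spread (:func:`stwrs_test`);
* the paired sign-flip Wilcoxon signed-rank test (:func:`wsr_test`);
* Benjamini-Hochberg FDR adjustment (:func:`fdr_adjust`);
* a median-regression screen for sex and age effects
  (:func:`sexage_screen`);
* consecutive-epoch trend scans (:func:`epoch_pair_trends`) and the
  count-based sensitivity grading of the within-subject indicators
  (:func:`sensitivity_scores`).

Every resampling test takes an explicit seed and reports Monte-Carlo
p-values with the add-one rule (b + 1)/(B + 1); with few enough
observations the permutation tests switch to exhaustive enumeration and
report exact p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "LongitudinalTestResult",
    "SensitivityReport",
    "ats_longitudinal",
    "ba_density_test",
    "jt_test",
    "ks_bootstrap_test",
    "stwrs_test",
    "wsr_test",
    "fdr_adjust",
    "sexage_screen",
    "epoch_pair_trends",
    "sensitivity_scores",
]

ALPHA = 0.05  # nominal significance level used throughout


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_resamples: int = 0
    seed: int | None = None
    p_adjusted: float | None = None
    exact: bool = False

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return p <= ALPHA


@dataclass
class EffectResult:
    statistic: float
    df1: float
    df2: float | None
    p_value: float


@dataclass
class LongitudinalTestResult:
    group_effect: EffectResult | None
    epoch_effect: EffectResult
    interaction: EffectResult | None


# ---------------------------------------------------------------------------
# Anova-type statistic (rank-based longitudinal ANOVA)
# ---------------------------------------------------------------------------

def _ats_from_projection(M: np.ndarray, phat: np.ndarray, V: np.ndarray, n: int):
    """ATS value and Box-approximation numerator df for projection M."""
    num = float(n * phat @ M @ phat)
    MV = M @ V
    tr = float(np.trace(MV))
    if tr <= 0:
        raise ValueError("degenerate covariance in ATS")
    F = num / tr
    f1 = tr**2 / float(np.trace(MV @ MV))
    return F, f1, MV


def ats_longitudinal(
    values: pd.DataFrame,
    value_col: str,
    groups: bool = True,
) -> LongitudinalTestResult:
    """Rank-based ANOVA-type tests for a (group x) repeated-epoch design.

    ``values`` is a long table with columns subject, epoch, ``value_col``
    and (when ``groups`` is True) group.  All observations are mid-ranked
    jointly; cell relative effects and their subject-level covariance feed
    the ATS with Box-approximation degrees of freedom.  Whole-plot (group)
    p-values use an F reference with a Satterthwaite denominator df; the
    repeated-measures effects use F(f, inf).
    """
    wide = values.pivot_table(index="subject", columns="epoch", values=value_col)
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing epochs for subjects: {missing}")
    subjects = wide.index
    Tn = wide.shape[1]
    ranks = stats.rankdata(wide.to_numpy().ravel()).reshape(wide.shape)
    N = ranks.size
    Y = (ranks - 0.5) / N  # subject x epoch relative-effect contributions

    if not groups:
        n = Y.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        phat = Y.mean(axis=0)
        V = np.cov(Y, rowvar=False, ddof=1)
        PT = np.eye(Tn) - np.full((Tn, Tn), 1.0 / Tn)
        F, f1, _ = _ats_from_projection(PT, phat, V, n)
        p = float(stats.chi2.sf(f1 * F, f1))
        return LongitudinalTestResult(None, EffectResult(F, f1, None, p), None)

    glab = values.groupby("subject")["group"].first().reindex(subjects)
    labels = sorted(glab.unique())
    a = len(labels)
    if a != 2:
        raise ValueError("exactly 2 groups are supported")
    n_i = [int((glab == g).sum()) for g in labels]
    if min(n_i) < 2:
        raise ValueError("every group needs at least 2 subjects")
    n = sum(n_i)

    # cell means and block-diagonal covariance, group-major ordering
    phat = np.concatenate([Y[(glab == g).to_numpy()].mean(axis=0) for g in labels])
    V = np.zeros((a * Tn, a * Tn))
    for gi, g in enumerate(labels):
        Yg = Y[(glab == g).to_numpy()]
        Vg = np.cov(Yg, rowvar=False, ddof=1) * (n / n_i[gi])
        sl = slice(gi * Tn, (gi + 1) * Tn)
        V[sl, sl] = Vg

    Pa = np.eye(a) - np.full((a, a), 1.0 / a)
    Jt = np.full((Tn, Tn), 1.0 / Tn)
    PT = np.eye(Tn) - Jt
    M_group = np.kron(Pa, Jt)
    M_epoch = np.kron(np.full((a, a), 1.0 / a), PT)
    M_inter = np.kron(Pa, PT)

    # group (whole-plot): F(f1, f0) with Satterthwaite denominator df
    F_g, f1_g, MV = _ats_from_projection(M_group, phat, V, n)
    denom = 0.0
    for gi in range(a):
        sl = slice(gi * Tn, (gi + 1) * Tn)
        tr_i = float(np.trace(M_group[sl, sl] @ V[sl, sl]))
        denom += tr_i**2 / (n_i[gi] - 1)
    f0 = float(np.trace(M_group @ V)) ** 2 / denom if denom > 0 else np.inf
    p_g = float(stats.f.sf(F_g, f1_g, f0))
    group = EffectResult(F_g, f1_g, f0, p_g)

    effects = {}
    for name, M in (("epoch", M_epoch), ("interaction", M_inter)):
        F, f1, _ = _ats_from_projection(M, phat, V, n)
        effects[name] = EffectResult(F, f1, None, float(stats.chi2.sf(f1 * F, f1)))

    return LongitudinalTestResult(group, effects["epoch"], effects["interaction"])


# ---------------------------------------------------------------------------
# Two-sample battery
# ---------------------------------------------------------------------------

def _silverman(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate sample (zero spread)")
    return 0.9 * spread * x.size ** (-0.2)


def ba_density_test(
    x: Sequence[float], y: Sequence[float],
    n_permutations: int = 2000, seed: int = 0, grid_size: int = 128,
) -> TestResult:
    """Kernel-density permutation test of distribution equality.

    Statistic: integrated squared difference between Gaussian kernel density
    estimates of the two samples at a common bandwidth (geometric mean of
    the samples' plug-in bandwidths).  The null distribution permutes group
    labels; p uses the add-one rule.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if min(n, m) < 5:
        raise ValueError("each sample needs at least 5 observations")
    h = float(np.sqrt(_silverman(x) * _silverman(y)))
    pooled = np.concatenate([x, y])
    lo, hi = pooled.min() - 3 * h, pooled.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    K = stats.norm.pdf((grid[None, :] - pooled[:, None]) / h) / h  # (n+m, G)

    def stat_from_rows(rows_x: np.ndarray) -> np.ndarray:
        fx = K[rows_x].mean(axis=-2)
        fsum = K.mean(axis=0) * (n + m)
        fy = (fsum - fx * n) / m
        return np.trapezoid((fx - fy) ** 2, grid, axis=-1)

    obs = float(stat_from_rows(np.arange(n)))
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_permutations, n + m)), axis=1)[:, :n]
    null = stat_from_rows(perm)
    p = (1.0 + float(np.sum(null >= obs - 1e-12))) / (n_permutations + 1.0)
    return TestResult("BA", obs, p, n_permutations, seed)


def _jt_statistic(samples: list[np.ndarray]) -> float:
    """Sum of pairwise Mann-Whitney counts over ordered group pairs."""
    J = 0.0
    for i, j in itertools.combinations(range(len(samples)), 2):
        a, b = samples[i], samples[j]
        J += float(np.sum(a[:, None] < b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))
    return J


def _enumerate_assignments(n_total: int, sizes: list[int]):
    """Yield index arrays per group for every distinct assignment."""
    idx = np.arange(n_total)

    def rec(avail: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(avail, k):
            rest = tuple(v for v in avail if v not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield [np.array(combo)] + tail

    yield from rec(tuple(idx), sizes)


def jt_test(
    samples: Sequence[Sequence[float]],
    n_permutations: int = 2000,
    seed: int = 0,
    alternative: Literal["two-sided", "increasing", "decreasing"] = "two-sided",
    exact_limit: int = 20000,
) -> TestResult:
    """Jonckheere-Terpstra permutation test for ordered alternatives.

    With two groups the statistic reduces to the Mann-Whitney U count.  When
    the number of distinct label assignments is at most ``exact_limit`` the
    permutation distribution is enumerated exhaustively (exact p),
    otherwise it is sampled.
    """
    groups = [np.asarray(s, float) for s in samples]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    obs = _jt_statistic(groups)

    from math import comb, prod
    n_arr = prod(
        comb(sum(sizes[i:]), sizes[i]) for i in range(len(sizes))
    )

    def tail(null: np.ndarray, exact: bool) -> float:
        eps = 1e-9
        if alternative == "increasing":
            b = np.sum(null >= obs - eps)
        elif alternative == "decreasing":
            b = np.sum(null <= obs + eps)
        else:
            center = np.mean(null)
            b = np.sum(np.abs(null - center) >= abs(obs - center) - eps)
        if exact:
            return float(b) / null.size
        return (1.0 + float(b)) / (null.size + 1.0)

    if n_arr <= exact_limit:
        null = np.array([
            _jt_statistic([pooled[ix] for ix in assign])
            for assign in _enumerate_assignments(n_total, sizes)
        ])
        return TestResult("JT", obs, tail(null, exact=True), null.size, seed, exact=True)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start:start + s])
            start += s
        null[b] = _jt_statistic(parts)
    return TestResult("JT", obs, tail(null, exact=False), n_permutations, seed)


def _ks_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """KS sup-distance plus a Cramer-von-Mises-type secondary key.

    The sup-distance at small n is lattice-valued (multiples of 1/n); the
    integrated squared ECDF difference refines the ordering so the
    Monte-Carlo null comparison is effectively tie-free.
    """
    sx, sy = np.sort(x), np.sort(y)
    allv = np.concatenate([sx, sy])
    cx = np.searchsorted(sx, allv, side="right") / sx.size
    cy = np.searchsorted(sy, allv, side="right") / sy.size
    d = np.abs(cx - cy)
    return float(d.max()), float((d**2).sum())


def ks_bootstrap_test(
    x: Sequence[float], y: Sequence[float], n_boot: int = 1000, seed: int = 0,
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test with a pooled-resampling null.

    The sup-distance statistic keeps its usual definition; the null
    distribution redraws both samples with replacement from the pooled
    sample, which keeps the reference distribution honest in the presence
    of ties (the reason for bootstrapping instead of the asymptotic null).
    The sup-distance at small n is lattice-valued, so null comparisons are
    ordered lexicographically by (sup-distance, integrated squared ECDF
    difference): the reported statistic and its meaning are unchanged, but
    the comparison is effectively tie-free and the test calibrates at the
    nominal level instead of snapping to the nearest lattice atom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if min(n, m) < 5:
        raise ValueError("each sample needs at least 5 observations")
    obs_d, obs_w = _ks_stat(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    eps = 1e-12
    b_ge = 0
    for _ in range(n_boot):
        draw = rng.choice(pooled, n + m, replace=True)
        d, w = _ks_stat(draw[:n], draw[n:])
        if d > obs_d + eps or (abs(d - obs_d) <= eps and w >= obs_w - eps):
            b_ge += 1
    p = (1.0 + b_ge) / (n_boot + 1.0)
    return TestResult("KS-boot", obs_d, p, n_boot, seed)


def _bm_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Brunner-Munzel studentized rank-sum statistic (unequal-spread robust)."""
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    R = stats.rankdata(pooled)
    Rx, Ry = R[:n1], R[n1:]
    rx_in = stats.rankdata(x)
    ry_in = stats.rankdata(y)
    mx, my = Rx.mean(), Ry.mean()
    s1 = np.sum((Rx - rx_in - mx + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    s2 = np.sum((Ry - ry_in - my + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    denom = N * np.sqrt(n1 * s1 + n2 * s2)
    if denom == 0:
        # complete separation (zero placement variance): maximally extreme
        return float(np.sign(my - mx) * np.inf) if my != mx else 0.0
    return float(n1 * n2 * (my - mx) / denom)


def stwrs_test(
    x: Sequence[float], y: Sequence[float],
    n_permutations: int = 2000, seed: int = 0, exact_limit: int = 8,
) -> TestResult:
    """Studentized Wilcoxon rank-sum permutation test (two-sided).

    The rank-sum is centered and scaled by a Brunner-Munzel-type variance
    estimate built from placements, which keeps the permutation test
    calibrated under unequal spreads.  With at most ``exact_limit`` total
    observations the label assignments are enumerated exhaustively.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if min(n, m) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("degenerate samples (all values identical)")
    obs = _bm_statistic(x, y)
    pooled = np.concatenate([x, y])

    if n + m <= exact_limit:
        null = np.array([
            _bm_statistic(pooled[list(ix)], np.delete(pooled, list(ix)))
            for ix in itertools.combinations(range(n + m), n)
        ])
        p = float(np.sum(np.abs(null) >= abs(obs) - 1e-12)) / null.size
        return TestResult("StWRS", obs, p, null.size, seed, exact=True)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(pooled)
        null[b] = _bm_statistic(perm[:n], perm[n:])
    p = (1.0 + float(np.sum(np.abs(null) >= abs(obs) - 1e-12))) / (n_permutations + 1.0)
    return TestResult("StWRS", obs, p, n_permutations, seed)


def wsr_test(
    before: Sequence[float], after: Sequence[float],
    n_permutations: int = 2000, seed: int = 0,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    exact_limit: int = 12,
) -> TestResult:
    """Sign-flip permutation Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; the statistic is the positive-rank sum
    W+.  With at most ``exact_limit`` non-zero pairs all 2^n sign patterns
    are enumerated (exact p); otherwise random sign flips with the add-one
    rule.
    """
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero differences")
    r = stats.rankdata(np.abs(d))
    w_obs = float(r[d > 0].sum())
    mu = r.sum() / 2.0

    def tail(null: np.ndarray, exact: bool) -> float:
        eps = 1e-9
        if alternative == "greater":
            b = np.sum(null >= w_obs - eps)
        elif alternative == "less":
            b = np.sum(null <= w_obs + eps)
        else:
            b = np.sum(np.abs(null - mu) >= abs(w_obs - mu) - eps)
        if exact:
            return float(b) / null.size
        return (1.0 + float(b)) / (null.size + 1.0)

    if n <= exact_limit:
        patterns = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        null = (patterns * r[None, :]).sum(axis=1).astype(float)
        return TestResult("WSR", w_obs, tail(null, exact=True), null.size, seed, exact=True)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, n))
    null = (signs * r[None, :]).sum(axis=1).astype(float)
    return TestResult("WSR", w_obs, tail(null, exact=False), n_permutations, seed)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Sex/age screen
# ---------------------------------------------------------------------------

def sexage_screen(
    values: Sequence[float],
    sex: Sequence[int],
    age: Sequence[float],
    tau: float = 0.5,
) -> dict[str, TestResult]:
    """Median-regression screen for sex, age and sex-by-age effects.

    Fits a quantile regression of the indicator on sex (0 = female,
    1 = male), age and their interaction, and tests each coefficient.
    This screen only reports; it never adjusts the indicator.  With a
    single-sex sample the sex and interaction terms are dropped with a
    warning.
    """
    import statsmodels.api as sm
    from statsmodels.regression.quantile_regression import QuantReg

    y = np.asarray(values, float)
    sex = np.asarray(sex, float)
    age = np.asarray(age, float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    terms = {"sex": sex, "age": age, "sex:age": sex * age}
    if np.unique(sex).size < 2:
        warnings.warn("single-sex sample: dropping sex and interaction terms")
        terms = {"age": age}
    X = sm.add_constant(pd.DataFrame(terms))
    fit = QuantReg(y, X).fit(q=tau)
    out = {}
    for term in terms:
        out[term] = TestResult(
            method=f"quantreg(tau={tau})",
            statistic=float(fit.tvalues[term]),
            p_value=float(fit.pvalues[term]),
        )
    return out


# ---------------------------------------------------------------------------
# Epoch-pair trends and sensitivity grading
# ---------------------------------------------------------------------------

def epoch_pair_trends(
    ws_table: pd.DataFrame,
    indicator: str,
    n_permutations: int = 2000,
    seed: int = 0,
    n_epochs: int = 9,
) -> pd.DataFrame:
    """Consecutive-epoch comparisons of one WS indicator (whole sample).

    For each of the ``n_epochs - 1`` consecutive epoch pairs both the ATS
    (two-epoch repeated-measures) and the paired WSR test are run;
    Benjamini-Hochberg adjustment is applied across the pairs separately
    per test family.  Returns a tidy frame with one row per (pair, method).
    """
    epochs = sorted(ws_table["epoch"].unique())
    if epochs != list(range(1, n_epochs + 1)):
        raise ValueError(f"expected epochs 1..{n_epochs}, found {epochs}")
    wide = ws_table.pivot_table(index="subject", columns="epoch", values=indicator)
    if wide.isna().any().any():
        raise ValueError("missing subject-epoch values")
    rows = []
    for j, (t0, t1) in enumerate(itertools.pairwise(range(1, n_epochs + 1))):
        sub = ws_table[ws_table["epoch"].isin([t0, t1])]
        ats = ats_longitudinal(sub, indicator, groups=False)
        wsr = wsr_test(
            wide[t0].to_numpy(), wide[t1].to_numpy(),
            n_permutations=n_permutations, seed=seed + j,
        )
        direction = "increase" if wide[t1].median() > wide[t0].median() else "decrease"
        rows.append({"pair": f"{t0}-{t1}", "method": "ATS",
                     "statistic": ats.epoch_effect.statistic,
                     "p": ats.epoch_effect.p_value, "direction": direction})
        rows.append({"pair": f"{t0}-{t1}", "method": "WSR",
                     "statistic": wsr.statistic, "p": wsr.p_value,
                     "direction": direction})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for method in df["method"].unique():
        mask = df["method"] == method
        df.loc[mask, "p_adj"] = fdr_adjust(df.loc[mask, "p"].to_numpy())
    df["significant"] = df["p_adj"] <= ALPHA
    return df


@dataclass
class SensitivityConfig:
    """Count-to-level mapping for the sensitivity grading.

    A pair/epoch "qualifies" when at least ``min_concordant`` of its
    procedures are significant; the aspect level comes from the share of
    qualifying pairs/epochs: 0 -> none, below ``weak_upper`` -> weak, below
    ``medium_upper`` -> medium, otherwise strong.  For single-contrast
    aspects (rest-stand) the level maps directly from the count of
    significant procedures: all -> strong, at least half -> medium, any ->
    weak, none -> none.
    """

    min_concordant: int = 2
    weak_upper: float = 1 / 3
    medium_upper: float = 2 / 3


@dataclass
class SensitivityReport:
    levels: dict[str, dict[str, str]]            # indicator -> aspect -> level
    details: dict[str, dict[str, dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"levels": self.levels, "details": self.details}


def _count_level(n_sig: int, n_proc: int, cfg: SensitivityConfig) -> str:
    if n_sig == 0:
        return "none"
    if n_sig == n_proc:
        return "strong"
    return "medium" if n_sig >= n_proc / 2 else "weak"


def _share_level(share: float, cfg: SensitivityConfig) -> str:
    if share == 0:
        return "none"
    if share < cfg.weak_upper:
        return "weak"
    if share < cfg.medium_upper:
        return "medium"
    return "strong"


def sensitivity_scores(
    battery: dict[str, dict[str, dict]],
    config: SensitivityConfig | None = None,
) -> SensitivityReport:
    """Grade each WS indicator's sensitivity per aspect from test outcomes.

    ``battery[indicator]`` holds three aspects:

    * ``"rest-stand"``: mapping procedure-name -> bool (significant);
    * ``"exercise-fraction"``: mapping pair-label -> {procedure: bool};
    * ``"sports-specialties"``: ``{"overall": {procedure: bool},
      "epochs": {epoch-label: {procedure: bool}}}``.

    Levels follow the count-based convention: for the single rest-stand
    contrast the number of concordant significant procedures maps directly
    to none/weak/medium/strong; for multi-contrast aspects a pair or epoch
    qualifies with >= ``min_concordant`` significant procedures and the
    level reflects the share of qualifying contrasts.  Qualifying contrasts
    are annotated "all tests significant" vs "at least two significant".
    An aspect with no recorded outcomes is marked not-evaluable.
    """
    cfg = config or SensitivityConfig()
    levels: dict[str, dict[str, str]] = {}
    details: dict[str, dict[str, dict]] = {}
    for ind, aspects in battery.items():
        levels[ind] = {}
        details[ind] = {}
        # rest-stand: single contrast
        rs = aspects.get("rest-stand")
        if not rs:
            levels[ind]["rest-stand"] = "not-evaluable"
        else:
            n_sig = sum(bool(v) for v in rs.values())
            levels[ind]["rest-stand"] = _count_level(n_sig, len(rs), cfg)
            details[ind]["rest-stand"] = {"n_significant": n_sig, "n_procedures": len(rs)}
        # exercise fraction: consecutive pairs
        ex = aspects.get("exercise-fraction")
        if not ex:
            levels[ind]["exercise-fraction"] = "not-evaluable"
        else:
            qualifying, annot = [], {}
            for pair, procs in ex.items():
                n_sig = sum(bool(v) for v in procs.values())
                if n_sig >= cfg.min_concordant:
                    qualifying.append(pair)
                    annot[pair] = (
                        "all tests significant" if n_sig == len(procs)
                        else "at least two significant"
                    )
            share = len(qualifying) / len(ex)
            levels[ind]["exercise-fraction"] = _share_level(share, cfg)
            details[ind]["exercise-fraction"] = {"qualifying_pairs": annot}
        # sports specialties: per-epoch batteries gated by the overall tests
        sp = aspects.get("sports-specialties")
        if not sp:
            levels[ind]["sports-specialties"] = "not-evaluable"
        else:
            overall = sp.get("overall", {})
            epochs = sp.get("epochs", {})
            qualifying, annot = [], {}
            for ep, procs in epochs.items():
                n_sig = sum(bool(v) for v in procs.values())
                if n_sig >= cfg.min_concordant:
                    qualifying.append(ep)
                    annot[ep] = (
                        "all tests significant" if n_sig == len(procs)
                        else "at least two significant"
                    )
            share = len(qualifying) / len(epochs) if epochs else 0.0
            level = _share_level(share, cfg)
            if overall and not any(overall.values()):
                level = "none"
            levels[ind]["sports-specialties"] = level
            details[ind]["sports-specialties"] = {
                "overall": overall, "qualifying_epochs": annot,
            }
    return SensitivityReport(levels=levels, details=details)
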