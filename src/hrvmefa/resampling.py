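"""Stratified balanced bootstrap over subjects with BCa intervals.

The resampling unit is the *subject*: a drawn subject contributes all of
its epochs, so the within-subject dependence structure is never broken.
Samples are balanced within stratum -- across the whole plan every subject
appears exactly B times -- and preserve stratum (group) sizes, so the two
groups enter each bootstrap sample in their original proportion.

Factor-analysis replicates need special handling: a replicate whose
principal-axis solution turns Heywood (some communality > 1) is discarded
and counted; admissible replicates are aligned to the original solution by
greedy Tucker-congruence matching with sign flips before aggregation, and
replicates with an unmatched factor (congruence below threshold) are
discarded separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from hrvmefa import mefa as _mefa
from hrvmefa.mefa import MefaConfig, MefaResult, fit_mefa, pkde_transform

__all__ = [
    "BootstrapPlan",
    "BootstrapSummary",
    "make_plan",
    "bca_interval",
    "tucker_congruence",
    "align_loadings",
    "bootstrap_mefa",
    "MefaBootstrap",
]


@dataclass
class BootstrapPlan:
    """Balanced-within-stratum subject resampling design."""

    B: int
    strata: pd.Series               # subject -> stratum label
    index_matrix: np.ndarray        # B x n array of subject positions
    seed: int
    subjects: np.ndarray = field(default=None)

    def validate(self) -> None:
        counts = np.bincount(self.index_matrix.ravel(), minlength=len(self.subjects))
        if not np.all(counts == self.B):
            raise AssertionError("plan is not balanced: unequal subject counts")


def make_plan(strata: pd.Series | dict, B: int, seed: int = 0) -> BootstrapPlan:
    """Build a balanced stratified bootstrap plan.

    Within each stratum, B copies of the subject list are concatenated,
    shuffled, and partitioned into B samples; every subject therefore
    appears exactly B times over the plan and each sample preserves stratum
    sizes.  Deterministic given the seed.
    """
    strata = pd.Series(strata)
    subjects = strata.index.to_numpy()
    pos = {s: i for i, s in enumerate(subjects)}
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    for stratum in pd.unique(strata.values):
        members = [pos[s] for s in strata.index[strata == stratum]]
        if len(members) == 0:
            raise ValueError(f"empty stratum {stratum!r}")
        if len(members) == 1:
            warnings.warn(f"stratum {stratum!r} has a single subject: degenerate resampling")
        tickets = np.tile(members, B)
        rng.shuffle(tickets)
        cols.append(tickets.reshape(B, len(members)))
    index_matrix = np.hstack(cols)
    plan = BootstrapPlan(B=B, strata=strata, index_matrix=index_matrix,
                         seed=seed, subjects=subjects)
    plan.validate()
    return plan


@dataclass
class BootstrapSummary:
    """Point estimate with BCa (or fallback percentile) interval."""

    estimate: np.ndarray | float
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    level: float
    n_retained: int
    n_discarded: int
    discard_reason: str = ""


def bca_interval(
    estimate: float,
    replicates: np.ndarray,
    jackknife: np.ndarray | None = None,
    influence: np.ndarray | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for one scalar.

    Bias correction ``z0`` comes from the fraction of replicates below the
    point estimate; acceleration from leave-one-out jackknife values, or
    from empirical influence values when supplied (the infinitesimal
    jackknife form ``a = sum(U^3) / (6 (sum U^2)^{3/2})``).  When all
    replicates fall on one side of the estimate ``z0`` is undefined and the
    plain percentile interval is returned with a warning; identical
    replicates give a degenerate interval.
    """
    reps = np.asarray(replicates, float)
    B = reps.size
    if B < 100:
        raise ValueError("need at least 100 retained replicates for a BCa interval")
    if np.ptp(reps) == 0:
        return float(reps[0]), float(reps[0])
    alpha = (1.0 - level) / 2.0
    frac = (np.sum(reps < estimate) + 0.5 * np.sum(reps == estimate)) / B
    if frac <= 0.0 or frac >= 1.0:
        warnings.warn("all replicates on one side of the estimate: percentile fallback")
        return tuple(np.quantile(reps, [alpha, 1 - alpha]).tolist())
    z0 = ndtri(frac)
    if influence is not None:
        U = np.asarray(influence, float)
        num, den = np.sum(U**3), np.sum(U**2) ** 1.5
    elif jackknife is not None:
        jk = np.asarray(jackknife, float)
        d = jk.mean() - jk
        num, den = np.sum(d**3), np.sum(d**2) ** 1.5
    else:
        num, den = 0.0, 1.0
    a = num / (6.0 * den) if den > 0 else 0.0
    zlo, zhi = ndtri(alpha), ndtri(1.0 - alpha)
    qlo = ndtr(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    qhi = ndtr(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    lo, hi = np.quantile(reps, [qlo, qhi])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Factor alignment
# ---------------------------------------------------------------------------

def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between loading columns."""
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    na = np.sqrt((A**2).sum(axis=0))
    nb = np.sqrt((B**2).sum(axis=0))
    return (A.T @ B) / np.outer(na, nb)


def align_loadings(
    reference: np.ndarray, candidate: np.ndarray, threshold: float = 0.7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Greedily match candidate factors to the reference by |congruence|.

    Returns ``(aligned_loadings, permutation, signs)`` such that
    ``aligned[:, k] = signs[k] * candidate[:, permutation[k]]``, or None if
    any reference factor's best available match falls below ``threshold``.
    """
    C = tucker_congruence(reference, candidate)
    q = C.shape[0]
    perm = np.full(q, -1)
    signs = np.ones(q)
    used = np.zeros(q, dtype=bool)
    order = np.argsort(-np.abs(C).max(axis=1))  # strongest matches first
    for k in order:
        row = np.abs(C[k]).copy()
        row[used] = -np.inf
        j = int(np.argmax(row))
        if row[j] < threshold:
            return None
        perm[k] = j
        signs[k] = np.sign(C[k, j]) or 1.0
        used[j] = True
    aligned = candidate[:, perm] * signs
    return aligned, perm, signs


# ---------------------------------------------------------------------------
# MEFA bootstrap
# ---------------------------------------------------------------------------

@dataclass
class MefaBootstrap:
    """Aggregated bootstrap output of the two-level factor analysis."""

    bs_loadings: BootstrapSummary
    ws_loadings: BootstrapSummary
    bs_variance_pct: BootstrapSummary
    ws_variance_pct: BootstrapSummary
    kmo_b: BootstrapSummary
    kmo_w: BootstrapSummary
    ws_epoch_group_medians: dict[str, pd.DataFrame]
    bs_group_medians: dict[str, pd.DataFrame]
    n_heywood: int
    n_unmatched: int
    n_retained: int
    B: int
    seed: int


def _resample_panel(panel: pd.DataFrame, subjects: np.ndarray, draw: np.ndarray) -> pd.DataFrame:
    """Panel restricted to drawn subjects, with copies disambiguated."""
    by_subj = dict(tuple(panel.groupby("subject", sort=False)))
    parts = []
    for copy_i, pos in enumerate(draw):
        block = by_subj[subjects[pos]].copy()
        block["subject"] = f"{subjects[pos]}*{copy_i}"
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def _indicator_medians(res: MefaResult, perm_b, signs_b, perm_w, signs_w):
    """Per-group BS medians and per-epoch (overall + per-group) WS medians,
    computed on PKDE-rescored aligned factor scores."""
    bs_raw = res.bs_raw_scores[:, perm_b] * signs_b
    ws_raw = res.ws_raw_scores[:, perm_w] * signs_w
    bs_meta = res.indicators.bs_scores[["subject", "group"]]
    ws_meta = res.indicators.ws_scores[["subject", "group", "epoch"]]
    out_bs = {}
    for k in range(bs_raw.shape[1]):
        ind = pkde_transform(bs_raw[:, k])
        out_bs[k] = pd.Series(ind).groupby(bs_meta["group"].to_numpy()).median()
    out_ws = {}
    for k in range(ws_raw.shape[1]):
        ind = pd.Series(pkde_transform(ws_raw[:, k]))
        med_all = ind.groupby(ws_meta["epoch"].to_numpy()).median()
        med_grp = ind.groupby([ws_meta["group"].to_numpy(), ws_meta["epoch"].to_numpy()]).median()
        out_ws[k] = (med_all, med_grp)
    return out_bs, out_ws


def bootstrap_mefa(
    panel: pd.DataFrame,
    plan: BootstrapPlan,
    reference: MefaResult,
    config: MefaConfig | None = None,
    level: float = 0.95,
    congruence_threshold: float = 0.7,
    with_jackknife: bool = True,
    max_discard_frac: float = 0.5,
) -> MefaBootstrap:
    """Bootstrap the full MEFA fit under a balanced subject-level plan.

    Each replicate rebuilds the panel from the drawn subjects (all epochs),
    reruns decomposition, extraction and rotation at the reference factor
    counts, discards Heywood replicates, aligns the loadings to the
    reference solution, and aggregates.  BCa intervals use leave-one-
    subject-out jackknife values for the acceleration (disable with
    ``with_jackknife=False`` to fall back on the plain percentile-style
    acceleration-zero interval).
    """
    cfg = config or MefaConfig()
    q_b, q_w = reference.bs_solution.q, reference.ws_solution.q
    ref_b = reference.bs_solution.loadings
    ref_w = reference.ws_solution.loadings
    subjects = plan.subjects

    coll = {k: [] for k in ("bs_load", "ws_load", "bs_var", "ws_var", "kmo_b", "kmo_w")}
    med_bs_reps: dict[int, list] = {}
    med_ws_all_reps: dict[int, list] = {}
    med_ws_grp_reps: dict[int, list] = {}
    n_heywood = n_unmatched = 0

    def fit_one(sub_panel):
        return fit_mefa(sub_panel, q_b=q_b, q_w=q_w, config=cfg, on_heywood="flag")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(plan.B):
            sub = _resample_panel(panel, subjects, plan.index_matrix[b])
            try:
                res = fit_one(sub)
            except (np.linalg.LinAlgError, ValueError, RuntimeError):
                n_unmatched += 1
                continue
            if res.bs_solution.heywood or res.ws_solution.heywood:
                n_heywood += 1
                continue
            al_b = align_loadings(ref_b, res.bs_solution.loadings, congruence_threshold)
            al_w = align_loadings(ref_w, res.ws_solution.loadings, congruence_threshold)
            if al_b is None or al_w is None:
                n_unmatched += 1
                continue
            Lb, perm_b, signs_b = al_b
            Lw, perm_w, signs_w = al_w
            coll["bs_load"].append(Lb)
            coll["ws_load"].append(Lw)
            coll["bs_var"].append((Lb**2).sum(axis=0) * 100.0 / Lb.shape[0])
            coll["ws_var"].append((Lw**2).sum(axis=0) * 100.0 / Lw.shape[0])
            coll["kmo_b"].append(res.correlations.kmo_b)
            coll["kmo_w"].append(res.correlations.kmo_w)
            mb, mw = _indicator_medians(res, perm_b, signs_b, perm_w, signs_w)
            for k, v in mb.items():
                med_bs_reps.setdefault(k, []).append(v)
            for k, (ma, mg) in mw.items():
                med_ws_all_reps.setdefault(k, []).append(ma)
                med_ws_grp_reps.setdefault(k, []).append(mg)

    n_retained = len(coll["kmo_b"])
    n_discarded = plan.B - n_retained
    if n_discarded > max_discard_frac * plan.B:
        raise RuntimeError(
            f"too many discarded bootstrap replicates "
            f"({n_discarded}/{plan.B}: {n_heywood} Heywood, {n_unmatched} unmatched)"
        )

    # jackknife (leave-one-subject-out) for the acceleration constant
    jk = {k: [] for k in ("bs_load", "ws_load", "bs_var", "ws_var", "kmo_b", "kmo_w")}
    if with_jackknife:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in subjects:
                sub = panel[panel["subject"] != s]
                try:
                    res = fit_one(sub)
                except (np.linalg.LinAlgError, ValueError, RuntimeError):
                    continue
                if res.bs_solution.heywood or res.ws_solution.heywood:
                    continue
                al_b = align_loadings(ref_b, res.bs_solution.loadings, congruence_threshold)
                al_w = align_loadings(ref_w, res.ws_solution.loadings, congruence_threshold)
                if al_b is None or al_w is None:
                    continue
                jk["bs_load"].append(al_b[0])
                jk["ws_load"].append(al_w[0])
                jk["bs_var"].append((al_b[0] ** 2).sum(axis=0) * 100.0 / al_b[0].shape[0])
                jk["ws_var"].append((al_w[0] ** 2).sum(axis=0) * 100.0 / al_w[0].shape[0])
                jk["kmo_b"].append(res.correlations.kmo_b)
                jk["kmo_w"].append(res.correlations.kmo_w)

    def summarize(est: np.ndarray | float, reps_list: list, jk_list: list, reason: str):
        reps = np.asarray(reps_list, float)
        est_arr = np.asarray(est, float)
        jk_arr = np.asarray(jk_list, float) if jk_list else None
        lo = np.empty_like(est_arr, dtype=float)
        hi = np.empty_like(est_arr, dtype=float)
        it = np.ndindex(est_arr.shape) if est_arr.shape else [()]
        for ix in it:
            r = reps[(slice(None),) + ix] if est_arr.shape else reps
            j = jk_arr[(slice(None),) + ix] if (jk_arr is not None and est_arr.shape) else jk_arr
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                l, h = bca_interval(float(est_arr[ix]) if est_arr.shape else float(est_arr),
                                    r, jackknife=j, level=level)
            if est_arr.shape:
                lo[ix], hi[ix] = l, h
            else:
                lo, hi = l, h
        return BootstrapSummary(
            estimate=est, ci_low=lo, ci_high=hi, level=level,
            n_retained=n_retained, n_discarded=n_discarded, discard_reason=reason,
        )

    reason = f"{n_heywood} Heywood, {n_unmatched} unmatched/failed"
    summaries = dict(
        bs_loadings=summarize(ref_b, coll["bs_load"], jk["bs_load"], reason),
        ws_loadings=summarize(ref_w, coll["ws_load"], jk["ws_load"], reason),
        bs_variance_pct=summarize(reference.bs_solution.variance_pct,
                                  coll["bs_var"], jk["bs_var"], reason),
        ws_variance_pct=summarize(reference.ws_solution.variance_pct,
                                  coll["ws_var"], jk["ws_var"], reason),
        kmo_b=summarize(reference.correlations.kmo_b, coll["kmo_b"], jk["kmo_b"], reason),
        kmo_w=summarize(reference.correlations.kmo_w, coll["kmo_w"], jk["kmo_w"], reason),
    )

    # percentile CIs for indicator medians (per BS group; per WS epoch)
    def med_frame(reps_list: list) -> pd.DataFrame:
        mat = pd.concat(reps_list, axis=1)
        lo = mat.quantile((1 - level) / 2, axis=1)
        hi = mat.quantile(1 - (1 - level) / 2, axis=1)
        med = mat.median(axis=1)
        return pd.DataFrame({"median": med, "ci_low": lo, "ci_high": hi})

    bs_names = list(reference.indicators.bs_scores.columns[2:])
    ws_names = list(reference.indicators.ws_scores.columns[3:])
    bs_group_medians = {bs_names[k]: med_frame(v) for k, v in med_bs_reps.items()}
    ws_epoch_group_medians = {}
    for k, v in med_ws_all_reps.items():
        overall = med_frame(v)
        grouped = med_frame(med_ws_grp_reps[k])
        ws_epoch_group_medians[ws_names[k]] = pd.concat(
            [overall.assign(scope="all"), grouped.assign(scope="group")]
        )

    return MefaBootstrap(
        **summaries,
        ws_epoch_group_medians=ws_epoch_group_medians,
        bs_group_medians=bs_group_medians,
        n_heywood=n_heywood,
        n_unmatched=n_unmatched,
        n_retained=n_retained,
        B=plan.B,
        seed=plan.seed,
    )
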