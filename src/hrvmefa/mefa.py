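"""Two-level exploratory factor analysis of the proxy panel.

The panel ``X_ijt`` (subject *i*, proxy *j*, epoch *t*) is split into a
between-subject (BS) part -- the subject averages over epochs -- and a
within-subject (WS) part -- the subject-centered values.  Pearson
correlations of the two parts give the BS correlation matrix ``R_B``
(inter-individual structure, n subjects) and the pooled-WS correlation
matrix ``R_W`` (intra-individual structure, n*T centered rows).  Each matrix
is factored separately by iterated principal-axis extraction with varimax
rotation; factor adequacy is screened with the Kaiser-Meyer-Olkin index.

Rotated factors are interpreted from their >= 0.6 loadings (amplitude,
frequency, signal-self-similarity, oscillatory domains), scored by the
Thurstone regression method, and re-expressed through the cumulative
distribution of a Gaussian kernel density estimate ("PKDE") into indicators
on the [0, 100] scale.  The PKDE step preserves ranks exactly; only the
spacing between scores changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from hrvmefa.proxies import PROXY_NAMES, TIME_BASED

__all__ = [
    "CorrelationPair",
    "FactorSolution",
    "IndicatorSet",
    "MefaConfig",
    "MefaResult",
    "HeywoodError",
    "decompose_panel",
    "kmo",
    "principal_factor",
    "varimax_rotate",
    "choose_n_factors",
    "factor_scores",
    "pkde_transform",
    "summarize_solution",
    "label_factors",
    "fit_mefa",
]


class HeywoodError(RuntimeError):
    """An estimated communality exceeded 1 (inadmissible solution)."""


@dataclass
class CorrelationPair:
    """BS and pooled-WS correlation matrices with adequacy measures."""

    R_B: np.ndarray
    R_W: np.ndarray
    n_between: int
    n_within: int
    kmo_b: float
    kmo_w: float
    variable_names: tuple[str, ...] = PROXY_NAMES


@dataclass
class FactorSolution:
    """Rotated loading matrix with communalities and variance accounting."""

    level: Literal["BS", "WS"]
    loadings: np.ndarray          # p x q, proxies' correlations with factors
    communalities: np.ndarray     # length p
    variance_pct: np.ndarray      # per factor, % of total variance (= p)
    cumulative_pct: np.ndarray
    communality_share_pct: np.ndarray
    total_communality: float
    q: int
    heywood: bool = False
    variable_names: tuple[str, ...] = PROXY_NAMES
    labels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        cols = self.labels if self.labels else tuple(
            f"{self.level} factor {k + 1}" for k in range(self.q)
        )
        df = pd.DataFrame(self.loadings, index=list(self.variable_names), columns=list(cols))
        df["communality"] = self.communalities
        return df


@dataclass
class IndicatorSet:
    """PKDE-transformed factor scores on the [0, 100] scale."""

    bs_scores: pd.DataFrame       # subject, group + one column per BS indicator
    ws_scores: pd.DataFrame       # subject, group, epoch + one column per WS indicator
    label_map: dict[str, str]     # "BS factor 1" -> "AMP-BS-Ind", ...


@dataclass
class MefaConfig:
    """Knobs of the two-level factor analysis.

    ``eigen_threshold`` applies to the eigenvalues of the SMC-reduced
    correlation matrix; ``marker_threshold`` is the |loading| level a factor
    must reach on at least one proxy to count as interpretable;
    ``cum_var_floor`` is a reporting floor on cumulative explained variance.
    """

    eigen_threshold: float = 0.5
    cum_var_floor: float = 50.0
    marker_threshold: float = 0.6
    max_iter: int = 1000
    tol: float = 1e-3
    kmo_floor: float = 0.6


# ---------------------------------------------------------------------------
# Panel decomposition
# ---------------------------------------------------------------------------

def decompose_panel(
    panel: pd.DataFrame, variables: Sequence[str] = PROXY_NAMES
) -> tuple[pd.DataFrame, pd.DataFrame, CorrelationPair]:
    """Split the panel into subject averages and subject-centered values.

    Returns ``(xbar, xtilde, CorrelationPair)`` where ``xbar`` has one row
    per subject (epoch means) and ``xtilde`` one row per subject-epoch with
    each subject's own means removed (so per-subject column means of
    ``xtilde`` are exactly zero).  ``R_B`` is the Pearson correlation of the
    ``xbar`` columns, ``R_W`` the correlation of the pooled ``xtilde`` rows.
    """
    variables = list(variables)
    n = panel["subject"].nunique()
    T = panel["epoch"].nunique()
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if T < 2:
        raise ValueError("need at least 2 epochs")
    if panel[variables].isna().any().any():
        raise ValueError("panel contains missing proxies; apply a missing-policy first")

    grouped = panel.groupby("subject", sort=True)
    xbar = grouped[variables].mean()
    xbar.insert(0, "group", grouped["group"].first())

    xt = panel.sort_values(["subject", "epoch"]).reset_index(drop=True).copy()
    xt[variables] = xt[variables] - xt.groupby("subject")[variables].transform("mean")

    for lvl, df in (("BS", xbar[variables]), ("WS", xt[variables])):
        sd = df.std(ddof=0)
        dead = sd[sd == 0].index.tolist()
        if dead:
            raise ValueError(f"zero-variance column(s) at {lvl} level: {', '.join(dead)}")

    R_B = _smooth_correlation(np.corrcoef(xbar[variables].to_numpy(), rowvar=False), "BS")
    R_W = _smooth_correlation(np.corrcoef(xt[variables].to_numpy(), rowvar=False), "WS")
    pair = CorrelationPair(
        R_B=R_B, R_W=R_W, n_between=n, n_within=n * T,
        kmo_b=kmo(R_B), kmo_w=kmo(R_W), variable_names=tuple(variables),
    )
    return xbar, xt, pair


def _smooth_correlation(R: np.ndarray, level: str = "", floor: float = 1e-3) -> np.ndarray:
    """Eigenvalue-smooth a correlation matrix that is not positive definite.

    Proxy panels can contain (near-)deterministic pairs -- the normalized
    LF/HF units are exact complements whenever both bands carry power -- so
    the sample correlation matrix may be singular.  Eigenvalues below
    ``floor`` are raised to it and the matrix is rescaled to unit diagonal,
    the standard smoothing applied before inversion-based steps.
    """
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= floor:
        return R
    warnings.warn(
        f"{level or 'correlation'} matrix is nearly singular "
        f"(min eigenvalue {vals.min():.2e}); applying eigenvalue smoothing"
    )
    S = vecs @ np.diag(np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def kmo(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling-adequacy measure of a correlation matrix.

    ``sum r^2 / (sum r^2 + sum partial^2)`` over off-diagonal pairs, with
    partial correlations from the inverse correlation matrix.  Values below
    0.6 conventionally flag a poor factoring prospect.
    """
    R = np.asarray(R, dtype=float)
    try:
        A = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(A))
    partial = -A / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    ssr = float((R[off] ** 2).sum())
    ssp = float((partial[off] ** 2).sum())
    if ssr + ssp == 0:
        raise ValueError("no correlation structure (identity matrix)")
    return ssr / (ssr + ssp)


# ---------------------------------------------------------------------------
# Extraction, rotation, retention
# ---------------------------------------------------------------------------

def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (initial communality estimates)."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def principal_factor(
    R: np.ndarray, q: int, max_iter: int = 1000, tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterated principal-axis factoring.

    Starts from squared-multiple-correlation communalities, repeatedly
    eigendecomposes the reduced matrix (R with communalities on the
    diagonal) and keeps the top-``q`` components scaled by root eigenvalues.
    Returns ``(loadings, communalities, heywood)``; a communality above 1
    stops the iteration with the Heywood flag raised (the caller decides
    whether that aborts the fit or discards a bootstrap replicate).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if q < 1:
        raise ValueError("q must be >= 1")
    if q >= p:
        raise ValueError("q must be smaller than the number of variables")
    h = np.clip(_smc(R), 0.0, 1.0 - 1e-6)
    trace: list[float] = []
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:q]
        lam = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
        h_new = (lam**2).sum(axis=1)
        delta = float(np.max(np.abs(h_new - h)))
        trace.append(delta)
        h = h_new
        if delta < tol:
            # Heywood is judged on the converged solution: an excursion
            # above 1 that settles back is not inadmissible.
            return lam, h, bool(np.any(h > 1.0 + 1e-8))
    raise RuntimeError(
        f"principal-axis iteration did not converge in {max_iter} steps "
        f"(last deltas: {[f'{d:.2e}' for d in trace[-5:]]})"
    )


def varimax_rotate(
    loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-12,
) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalization.

    Communalities are preserved (orthogonality); output columns are ordered
    by explained variance and signed so the largest-magnitude loading in
    each column is positive.  A single factor cannot be rotated and is
    returned unchanged up to the ordering/sign convention.
    """
    L = np.asarray(loadings, dtype=float)
    p, q = L.shape
    if q >= 2:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        W = L / h[:, None]
        # Kaiser's pairwise sweeps: closed-form optimal planar angle per
        # factor pair, iterated until no pair moves (robust at the symmetric
        # saddle configurations where one-step SVD updates cycle)
        angle_tol = 1e-9
        for _ in range(max_iter):
            moved = 0.0
            for a in range(q - 1):
                for b in range(a + 1, q):
                    x, y = W[:, a], W[:, b]
                    u = x**2 - y**2
                    v = 2.0 * x * y
                    A, Bs = u.sum(), v.sum()
                    C = (u**2 - v**2).sum()
                    D = 2.0 * (u * v).sum()
                    num = D - 2.0 * A * Bs / p
                    den = C - (A**2 - Bs**2) / p
                    phi = 0.25 * np.arctan2(num, den)
                    if abs(phi) < angle_tol:
                        continue
                    moved = max(moved, abs(phi))
                    c, s = np.cos(phi), np.sin(phi)
                    W[:, a], W[:, b] = c * x + s * y, -s * x + c * y
            if moved < angle_tol:
                break
        L = W * h[:, None]
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return L * signs


def choose_n_factors(
    R: np.ndarray, config: MefaConfig | None = None
) -> tuple[int, dict]:
    """Retention rule: reduced-matrix eigenvalues + interpretability cap.

    Candidates are factors whose SMC-reduced eigenvalue exceeds
    ``config.eigen_threshold``; the candidate count is then reduced until
    every rotated factor carries at least one loading at or above
    ``config.marker_threshold`` in magnitude.  The returned rationale
    records the eigenvalues, the retained cumulative variance and whether it
    clears ``config.cum_var_floor``.
    """
    cfg = config or MefaConfig()
    R = np.asarray(R, dtype=float)
    Rr = R.copy()
    np.fill_diagonal(Rr, np.clip(_smc(R), 0.0, 1.0))
    eigvals = np.sort(np.linalg.eigvalsh(Rr))[::-1]
    q0 = int(np.sum(eigvals > cfg.eigen_threshold))
    if q0 == 0:
        raise ValueError(
            "no factor qualifies under the eigenvalue rule "
            f"(largest reduced eigenvalue {eigvals[0]:.3f} <= {cfg.eigen_threshold}); "
            "consider relaxing eigen_threshold"
        )
    q = q0
    pruned = []
    while q >= 1:
        lam, _, heywood = principal_factor(R, q, cfg.max_iter, cfg.tol)
        rot = varimax_rotate(lam)
        markers = np.abs(rot).max(axis=0) >= cfg.marker_threshold
        admissible = not heywood  # a Heywood candidate is inadmissible
        if (markers.all() and admissible) or q == 1:
            break
        pruned.append(q)
        q -= 1
    cum_pct = 100.0 * (rot**2).sum() / R.shape[0]
    rationale = {
        "eigenvalues": eigvals.tolist(),
        "eigen_threshold": cfg.eigen_threshold,
        "q_eigen_rule": q0,
        "q_after_interpretability": q,
        "pruned": pruned,
        "cumulative_variance_pct": float(cum_pct),
        "clears_cum_var_floor": bool(cum_pct >= cfg.cum_var_floor),
        "heywood": bool(heywood),
    }
    return q, rationale


# ---------------------------------------------------------------------------
# Scores, PKDE, summaries, labels
# ---------------------------------------------------------------------------

def factor_scores(Z: np.ndarray, loadings: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Thurstone regression scores ``Z @ R^-1 @ loadings``.

    ``Z`` must be standardized on the level's own scale (subject-average
    statistics for BS, pooled centered statistics for WS).
    """
    try:
        W = np.linalg.solve(R, loadings)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix in factor scoring") from exc
    return np.asarray(Z, dtype=float) @ W


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate (constant) scores: PKDE undefined")
    return 0.9 * spread * n ** (-0.2)


def pkde_transform(
    scores: Sequence[float],
    eval_at: Sequence[float] | None = None,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Kernel-CDF re-expression of factor scores onto [0, 100].

    The indicator is ``100 * F_hat(x)`` where ``F_hat`` is the exact CDF of
    a Gaussian kernel density estimate fitted to ``scores`` (Silverman
    plug-in bandwidth by default).  Strictly monotone in ``x``, hence
    rank-preserving.  ``eval_at`` defaults to the fitting sample itself.
    """
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct score values for PKDE")
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(x)
    at = x if eval_at is None else np.asarray(eval_at, dtype=float)
    F = ndtr((at[:, None] - x[None, :]) / h).mean(axis=1)
    return 100.0 * F


def summarize_solution(loadings: np.ndarray) -> dict[str, np.ndarray | float]:
    """Variance and communality accounting of a loading matrix.

    ``variance_pct`` is each factor's column sum of squares over the total
    variance p (the number of variables); ``communality_share_pct`` rescales
    by the total communality (the total reproduced variance).
    """
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    p = L.shape[0]
    ssq = (L**2).sum(axis=0)
    total_comm = float(ssq.sum())
    variance_pct = 100.0 * ssq / p
    share = 100.0 * ssq / total_comm if total_comm > 0 else np.full_like(ssq, np.nan)
    return {
        "variance_pct": variance_pct,
        "cumulative_pct": np.cumsum(variance_pct),
        "total_communality": total_comm,
        "communality_share_pct": share,
        "cumulative_communality_pct": np.cumsum(share),
    }


_DOMAIN_SHORT = {
    "Amplitude": "AMP",
    "Frequency": "FRE",
    "Signal Self-Similarity": "SSS",
    "Oscillatory": "OSC",
}


def label_factors(
    loadings: np.ndarray,
    level: str,
    variable_names: Sequence[str] = PROXY_NAMES,
    marker_threshold: float = 0.6,
) -> tuple[tuple[str, ...], dict[str, str]]:
    """Name factors by the proxy typology dominating their >= 0.6 loadings.

    A factor marked mostly by time-based proxies is the Amplitude domain;
    one marked only by {RR_Ro, P0v} is Signal Self-Similarity; one marked by
    {RR_LFnu, RR_HFnu} with opposite signs is Oscillatory; a mix of
    ratio-based markers is the broad Frequency domain.  Unresolvable factors
    keep a generic name with a warning.
    """
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    names = list(variable_names)
    time_set = set(TIME_BASED)
    labels = []
    for k in range(L.shape[1]):
        col = L[:, k]
        markers = {names[j]: col[j] for j in np.flatnonzero(np.abs(col) >= marker_threshold)}
        mk = set(markers)
        if not mk:
            warnings.warn(f"{level} factor {k + 1} has no loading >= {marker_threshold}; generic label")
            labels.append(f"Factor {k + 1}")
            continue
        n_time = len(mk & time_set)
        if n_time > len(mk) / 2:
            labels.append("Amplitude")
        elif mk <= {"RR_Ro", "P0v"}:
            labels.append("Signal Self-Similarity")
        elif mk == {"RR_LFnu", "RR_HFnu"} and markers["RR_LFnu"] * markers["RR_HFnu"] < 0:
            labels.append("Oscillatory")
        elif mk <= {"RR_LFnu", "RR_HFnu", "RR_Ro", "P0v"}:
            labels.append("Frequency")
        else:
            warnings.warn(f"{level} factor {k + 1} mixes typologies; generic label")
            labels.append(f"Factor {k + 1}")
    label_map = {}
    seen: dict[str, int] = {}
    for k, lab in enumerate(labels):
        short = _DOMAIN_SHORT.get(lab)
        ind = f"{short}-{level}-Ind" if short else f"F{k + 1}-{level}-Ind"
        if ind in label_map.values():  # disambiguate duplicated domains
            seen[ind] = seen.get(ind, 1) + 1
            ind = f"{ind}{seen[ind]}"
        label_map[f"{level} factor {k + 1}"] = ind
    return tuple(labels), label_map


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class MefaResult:
    correlations: CorrelationPair
    bs_solution: FactorSolution
    ws_solution: FactorSolution
    indicators: IndicatorSet
    bs_rationale: dict | None = None
    ws_rationale: dict | None = None
    xbar: pd.DataFrame | None = None
    xtilde: pd.DataFrame | None = None
    bs_raw_scores: np.ndarray | None = None
    ws_raw_scores: np.ndarray | None = None


def _build_solution(
    R: np.ndarray, q: int, level: str, cfg: MefaConfig,
    variable_names: tuple[str, ...], on_heywood: str,
) -> FactorSolution:
    lam, h, heywood = principal_factor(R, q, cfg.max_iter, cfg.tol)
    if heywood and on_heywood == "raise":
        bad = [variable_names[j] for j in np.flatnonzero(h > 1.0)]
        raise HeywoodError(
            f"{level} factoring produced communalities > 1 for: {', '.join(bad)}"
        )
    rot = varimax_rotate(lam)
    summ = summarize_solution(rot)
    labels, _ = label_factors(rot, level, variable_names, cfg.marker_threshold)
    return FactorSolution(
        level=level, loadings=rot, communalities=(rot**2).sum(axis=1),
        variance_pct=summ["variance_pct"], cumulative_pct=summ["cumulative_pct"],
        communality_share_pct=summ["communality_share_pct"],
        total_communality=summ["total_communality"], q=q, heywood=heywood,
        variable_names=variable_names, labels=labels,
    )


def fit_mefa(
    panel: pd.DataFrame,
    q_b: int | None = None,
    q_w: int | None = None,
    config: MefaConfig | None = None,
    variables: Sequence[str] = PROXY_NAMES,
    on_heywood: str = "raise",
) -> MefaResult:
    """End-to-end two-level factor analysis of a proxy panel.

    Factor counts are chosen by :func:`choose_n_factors` unless given.  The
    primary fit aborts on a Heywood case (``on_heywood="raise"``); bootstrap
    replicates pass ``"flag"`` so the caller can discard them.
    """
    cfg = config or MefaConfig()
    variables = tuple(variables)
    xbar, xt, pair = decompose_panel(panel, variables)
    for lvl, val in (("BS", pair.kmo_b), ("WS", pair.kmo_w)):
        if val < cfg.kmo_floor:
            warnings.warn(f"KMO at {lvl} level is {val:.3f} < {cfg.kmo_floor}: weak adequacy")

    bs_rat = ws_rat = None
    if q_b is None:
        q_b, bs_rat = choose_n_factors(pair.R_B, cfg)
    if q_w is None:
        q_w, ws_rat = choose_n_factors(pair.R_W, cfg)

    bs_sol = _build_solution(pair.R_B, q_b, "BS", cfg, variables, on_heywood)
    ws_sol = _build_solution(pair.R_W, q_w, "WS", cfg, variables, on_heywood)

    # level-specific standardization, then regression scoring
    xb = xbar[list(variables)].to_numpy()
    Zb = (xb - xb.mean(axis=0)) / xb.std(axis=0, ddof=0)
    bs_scores = factor_scores(Zb, bs_sol.loadings, pair.R_B)

    xw = xt[list(variables)].to_numpy()
    Zw = (xw - xw.mean(axis=0)) / xw.std(axis=0, ddof=0)
    ws_scores = factor_scores(Zw, ws_sol.loadings, pair.R_W)

    _, bs_map = label_factors(bs_sol.loadings, "BS", variables, cfg.marker_threshold)
    _, ws_map = label_factors(ws_sol.loadings, "WS", variables, cfg.marker_threshold)

    bs_df = pd.DataFrame({"subject": xbar.index, "group": xbar["group"].to_numpy()})
    for k, name in enumerate(bs_map.values()):
        bs_df[name] = pkde_transform(bs_scores[:, k])
    ws_df = xt[["subject", "group", "epoch"]].copy().reset_index(drop=True)
    for k, name in enumerate(ws_map.values()):
        ws_df[name] = pkde_transform(ws_scores[:, k])

    indicators = IndicatorSet(
        bs_scores=bs_df, ws_scores=ws_df, label_map={**bs_map, **ws_map}
    )
    return MefaResult(
        correlations=pair, bs_solution=bs_sol, ws_solution=ws_sol,
        indicators=indicators, bs_rationale=bs_rat, ws_rationale=ws_rat,
        xbar=xbar, xtilde=xt, bs_raw_scores=bs_scores, ws_raw_scores=ws_scores,
    )
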