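"""The 12 ANS proxies computed from each subject-epoch RR-interval series.

Proxies fall into two typologies.  *Time-based* variables carry a temporal
unit: heart rate (HR, beat/min), the RMS of the mean-centered tachogram
(RR_RMS, ms), total and band-limited autoregressive spectral powers (RR_TP,
RR_LFa, RR_HFa, ms^2), the RMS of successive differences (RMSSD, ms), and the
phase-rectified acceleration / deceleration capacities (AC, DC, ms).
*Ratio-based* variables are normalized: LF and HF powers in normalized units
(RR_LFnu, RR_HFnu, [0, 100]), the conditional-entropy regularity index
(RR_Ro, [0, 1]) and the share of zero-variation three-beat symbolic patterns
(P0v, [0, 100]).

Spectral analysis is autoregressive: the detrended tachogram is fitted on the
beat axis, the model order is chosen by Akaike's criterion, residual
whiteness is checked Anderson-style (a flag, not a failure), and the spectrum
is decomposed into components through the poles of the AR transfer function.
Central frequencies are converted from cycles/beat to Hz through the mean RR
interval.  Components are assigned to the LF band (0.03-0.15 Hz, open below)
or the HF band (0.15-0.40 Hz); components outside both bands count toward
total power only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROXY_NAMES",
    "TIME_BASED",
    "RATIO_BASED",
    "RRSeries",
    "ARSpectrum",
    "detrend_rr",
    "time_domain",
    "fit_ar_spectrum",
    "band_powers",
    "prsa",
    "quantize_series",
    "symbolic_pattern_shares",
    "symbolic_p0v",
    "regularity_ro",
    "compute_proxies",
    "compute_proxy_panel",
    "read_tachograms",
]

#: Canonical proxy column order used by every panel in the package.
PROXY_NAMES = (
    "HR", "RR_RMS", "RR_TP", "RR_LFa", "RR_HFa", "RR_LFnu",
    "RR_HFnu", "RMSSD", "AC", "DC", "RR_Ro", "P0v",
)
TIME_BASED = ("HR", "RR_RMS", "RR_TP", "RR_LFa", "RR_HFa", "RMSSD", "AC", "DC")
RATIO_BASED = ("RR_LFnu", "RR_HFnu", "RR_Ro", "P0v")

LF_BAND = (0.03, 0.15)   # Hz, open at the lower edge
HF_BAND = (0.15, 0.40)   # Hz, closed


@dataclass
class RRSeries:
    """One subject-epoch beat sequence (the raw input unit).

    ``rr`` holds consecutive RR intervals in milliseconds; every interval
    must be positive.  ``epoch_index`` runs 1-9 over the protocol (rest,
    stand, four exercise steps, peak, two recovery phases).
    """

    subject_id: str
    group: str
    epoch_index: int
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValueError("rr must be a 1-D sequence of intervals")
        if self.rr.size and np.any(self.rr <= 0):
            raise ValueError(
                f"non-positive RR interval in series "
                f"({self.subject_id}, epoch {self.epoch_index})"
            )

    @property
    def n_beats(self) -> int:
        return int(self.rr.size)


@dataclass
class ARSpectrum:
    """Autoregressive spectral decomposition of a detrended tachogram.

    ``components`` lists ``(central_frequency_hz, power_ms2)`` pairs obtained
    from the pole-residue decomposition of the AR transfer function; their
    powers sum to ``total_power`` (the process variance) up to numerical
    round-off.
    """

    order: int
    coefficients: np.ndarray
    innovation_variance: float
    components: list[tuple[float, float]]
    total_power: float
    mean_rr_ms: float
    whiteness_ok: bool = True

    def validate(self, tol: float = 0.01) -> None:
        s = sum(p for _, p in self.components)
        if self.total_power > 0 and abs(s - self.total_power) > tol * self.total_power:
            raise ValueError(
                f"component powers ({s:.4g}) do not sum to total power "
                f"({self.total_power:.4g}) within {tol:.0%}"
            )


def detrend_rr(rr: Sequence[float]) -> np.ndarray:
    """Remove the least-squares line over the beat index.

    Returns residuals with (numerically) zero mean; the caller keeps the
    original series for HR and the other time-domain statistics.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("detrending needs at least 3 beats")
    idx = np.arange(rr.size, dtype=float)
    slope, intercept = np.polyfit(idx, rr, 1)
    return rr - (slope * idx + intercept)


def time_domain(rr: Sequence[float]) -> tuple[float, float, float]:
    """Return ``(HR, RR_RMS, RMSSD)``.

    HR = 60000 / mean(rr) in beat/min; RR_RMS is the RMS of the mean-centered
    tachogram (its population SD); RMSSD the RMS of successive differences.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("time-domain statistics need at least 2 beats")
    hr = 60000.0 / float(np.mean(rr))
    rr_rms = float(np.sqrt(np.mean((rr - rr.mean()) ** 2)))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    return hr, rr_rms, rmssd


# ---------------------------------------------------------------------------
# Autoregressive spectral analysis
# ---------------------------------------------------------------------------

def _levinson(acov: np.ndarray, max_order: int):
    """Levinson-Durbin recursion; returns per-order (coefficients, sigma2)."""
    sigma2 = acov[0]
    coeffs: list[np.ndarray] = []
    sigmas: list[float] = []
    a = np.zeros(0)
    for k in range(1, max_order + 1):
        if sigma2 <= 0:
            break
        acc = acov[k] - (a @ acov[k - 1:0:-1] if k > 1 else 0.0)
        ref = acc / sigma2
        a_new = np.empty(k)
        a_new[:k - 1] = a - ref * a[::-1]
        a_new[k - 1] = ref
        a = a_new
        sigma2 = sigma2 * (1.0 - ref**2)
        coeffs.append(a.copy())
        sigmas.append(float(sigma2))
    return coeffs, sigmas


def _pole_residue_components(
    a: np.ndarray, sigma2: float, mean_rr_ms: float
) -> list[tuple[float, float]]:
    """Decompose the AR spectrum into components via pole residues.

    The spectral density S(z) = sigma2 / (A(z) A(1/z)) integrates over the
    unit circle to the process variance; the residue of S(z)/z at each pole
    inside the circle is the power attributable to that pole.  Complex
    conjugate pairs are merged into one oscillatory component whose central
    frequency is the pole angle in cycles/beat, converted to Hz by dividing
    by the mean RR interval in seconds.
    """
    p = a.size
    # P(z) = z^p - a1 z^{p-1} - ... - ap ; Q(z) = 1 - a1 z - ... - ap z^p
    pcoef = np.concatenate(([1.0], -a))
    roots = np.roots(pcoef)
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError("non-stationary AR fit: pole on or outside the unit circle")
    dP = np.polyval(np.polyder(pcoef), roots)
    qcoef = np.concatenate(([1.0], -a))[::-1]  # ascending -> np.polyval wants descending
    Q = np.polyval(qcoef, roots)
    residues = sigma2 * roots ** (p - 1) / (dP * Q)

    beat_s = mean_rr_ms / 1000.0
    comps: list[tuple[float, float]] = []
    used = np.zeros(p, dtype=bool)
    for i in range(p):
        if used[i]:
            continue
        z = roots[i]
        if abs(z.imag) < 1e-10:
            power = float(residues[i].real)
            freq_beat = 0.0 if z.real >= 0 else 0.5
            used[i] = True
        else:
            j = int(np.argmin(np.abs(roots - np.conj(z)) + used * 1e9))
            power = float((residues[i] + residues[j]).real)
            freq_beat = abs(float(np.angle(z))) / (2.0 * np.pi)
            used[i] = used[j] = True
        comps.append((freq_beat / beat_s, max(power, 0.0)))
    comps.sort(key=lambda c: c[0])
    return comps


def _anderson_whiteness(resid: np.ndarray, n_lags: int | None = None) -> bool:
    """Anderson-style whiteness check on residual autocorrelations.

    White if no more than ~5% of the inspected lags exceed the 95% bound
    +-1.96/sqrt(n) (one excursion is always tolerated).
    """
    n = resid.size
    if n_lags is None:
        n_lags = min(20, n // 5)
    r = resid - resid.mean()
    denom = float(r @ r)
    if denom == 0 or n_lags < 1:
        return True
    acf = np.array([float(r[k:] @ r[:-k]) / denom for k in range(1, n_lags + 1)])
    bound = 1.96 / np.sqrt(n)
    n_exceed = int(np.sum(np.abs(acf) > bound))
    return n_exceed <= max(1, int(np.ceil(0.05 * n_lags)))


def fit_ar_spectrum(
    rr_detrended: Sequence[float],
    mean_rr_ms: float,
    max_order: int = 16,
    min_order: int = 8,
) -> ARSpectrum:
    """Fit an AR model (Akaike order selection) and decompose its spectrum.

    ``rr_detrended`` must already be detrended; ``mean_rr_ms`` is the mean of
    the *original* series and fixes the beat-to-Hz conversion.  Orders
    ``min_order..max_order`` are searched by Yule-Walker/Levinson recursion
    and AIC; a non-stationary fit (pole on/outside the unit circle) is an
    error, a failed Anderson whiteness check only lowers ``whiteness_ok``.
    """
    x = np.asarray(rr_detrended, dtype=float)
    n = x.size
    if n < 4 * max_order:
        raise ValueError(f"series too short ({n}) for AR order search up to {max_order}")
    x = x - x.mean()
    var = float(x @ x) / n
    if var <= 0:
        raise ValueError("zero-variance series: no spectrum")
    acov = np.array(
        [float(x[k:] @ x[: n - k]) / n for k in range(max_order + 1)]
    )
    coeffs, sigmas = _levinson(acov, max_order)
    if len(coeffs) < min_order:
        raise ValueError("Levinson recursion terminated early (degenerate series)")
    orders = np.arange(1, len(coeffs) + 1)
    aic = n * np.log(np.maximum(sigmas, 1e-300)) + 2.0 * orders
    lo = min_order - 1
    best = lo + int(np.argmin(aic[lo:]))
    a, sigma2 = coeffs[best], sigmas[best]
    order = best + 1

    comps = _pole_residue_components(a, sigma2, mean_rr_ms)
    # residuals for the whiteness flag
    resid = x[order:] - np.column_stack(
        [x[order - m: n - m] for m in range(1, order + 1)]
    ) @ a
    spec = ARSpectrum(
        order=order,
        coefficients=a,
        innovation_variance=float(sigma2),
        components=comps,
        total_power=float(sum(p for _, p in comps)),
        mean_rr_ms=float(mean_rr_ms),
        whiteness_ok=_anderson_whiteness(resid),
    )
    return spec


def band_powers(
    spectrum: ARSpectrum,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> tuple[float, float, float, float, float]:
    """Return ``(RR_TP, RR_LFa, RR_HFa, RR_LFnu, RR_HFnu)``.

    Components with central frequency strictly inside ``(lf_lo, lf_hi)`` sum
    into LFa, inside ``[hf_lo, hf_hi]`` into HFa; components outside both
    bands contribute to total power only.  Normalized units follow the
    classic autoregressive-HRV convention ``100 * band / (TP - VLF)``: the
    denominator is the total component power above the lower LF edge, so
    supra-HF components (possible on fast tachograms, where the beat-axis
    Nyquist frequency exceeds 0.40 Hz) deflate both nu values and
    LFnu + HFnu <= 100 without being forced to equality.  When nothing lies
    above the VLF edge the nu pair is undefined and returned as NaN.
    """
    tp = spectrum.total_power
    lfa = hfa = denom = 0.0
    for f, p in spectrum.components:
        if f > lf_band[0]:
            denom += p
        if lf_band[0] < f < lf_band[1]:
            lfa += p
        elif hf_band[0] <= f <= hf_band[1]:
            hfa += p
    if denom > 0:
        lfnu = 100.0 * lfa / denom
        hfnu = 100.0 * hfa / denom
    else:
        lfnu = hfnu = float("nan")
    return tp, lfa, hfa, lfnu, hfnu


# ---------------------------------------------------------------------------
# Phase-rectified signal averaging
# ---------------------------------------------------------------------------

def prsa(
    rr: Sequence[float],
    anchor: Literal["acceleration", "deceleration"],
    window_L: int = 10,
    smoothing_s: int = 2,
    max_rel_change: float = 0.05,
) -> float:
    """Acceleration / deceleration capacity by phase-rectified averaging.

    Anchors are beats where RR decreases (acceleration) or increases
    (deceleration) relative to the previous beat, excluding changes larger
    than ``max_rel_change`` of the previous interval (artifact guard).
    Windows of +-``window_L`` beats are averaged over anchors into X(k) and
    the capacity is the Haar-wavelet contrast at scale ``smoothing_s``::

        ( sum_{k=0}^{s-1} X(k) - sum_{k=-s}^{-1} X(k) ) / (2 s)

    which for s = 2 is (X(0) + X(1) - X(-1) - X(-2)) / 4.  Returns NaN when
    no admissible anchor exists.
    """
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    if n <= 2 * window_L:
        raise ValueError("series shorter than the PRSA window")
    if smoothing_s > window_L:
        raise ValueError("smoothing scale cannot exceed the window half-length")
    diffs = np.diff(rr)
    if anchor == "acceleration":
        is_anchor = diffs < 0
    elif anchor == "deceleration":
        is_anchor = diffs > 0
    else:
        raise ValueError(f"unknown anchor type {anchor!r}")
    guard = np.abs(diffs) <= max_rel_change * rr[:-1]
    idx = np.flatnonzero(is_anchor & guard) + 1
    idx = idx[(idx >= window_L) & (idx <= n - 1 - window_L)]
    if idx.size == 0:
        return float("nan")
    offsets = np.arange(-window_L, window_L + 1)
    X = rr[idx[:, None] + offsets[None, :]].mean(axis=0)
    center = window_L
    s = smoothing_s
    pos = X[center: center + s].sum()
    neg = X[center - s: center].sum()
    return float((pos - neg) / (2.0 * s))


# ---------------------------------------------------------------------------
# Symbolic dynamics and regularity
# ---------------------------------------------------------------------------

def quantize_series(x: Sequence[float], n_levels: int = 6) -> np.ndarray:
    """Uniform quantization over the series' own min-max range.

    Ties at bin edges go to the lower bin; a zero-range series maps to a
    single symbol.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    sym = np.ceil(n_levels * (x - lo) / (hi - lo)).astype(int) - 1
    return np.clip(sym, 0, n_levels - 1)


def symbolic_pattern_shares(
    rr: Sequence[float], n_levels: int = 6, pattern_length: int = 3
) -> dict[int, float]:
    """Percent share of overlapping patterns by number of symbol changes.

    Keys are the variation counts 0..pattern_length-1; values sum to 100.
    """
    sym = quantize_series(rr, n_levels)
    if sym.size < pattern_length:
        raise ValueError("series shorter than the pattern length")
    n_pat = sym.size - pattern_length + 1
    windows = np.lib.stride_tricks.sliding_window_view(sym, pattern_length)
    changes = (np.diff(windows, axis=1) != 0).sum(axis=1)
    shares = {
        int(v): 100.0 * float(np.sum(changes == v)) / n_pat
        for v in range(pattern_length)
    }
    return shares


def symbolic_p0v(
    rr: Sequence[float], n_levels: int = 6, pattern_length: int = 3
) -> float:
    """Percentage of zero-variation symbolic patterns (P0v, [0, 100])."""
    return symbolic_pattern_shares(rr, n_levels, pattern_length)[0]


def _pattern_entropy(sym: np.ndarray, L: int) -> tuple[float, float]:
    """Shannon entropy of L-length patterns and the single-occurrence share."""
    windows = np.lib.stride_tricks.sliding_window_view(sym, L)
    _, counts = np.unique(windows, axis=0, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    perc_single = float(np.sum(counts == 1)) / counts.sum()
    return ent, perc_single


def regularity_ro(
    rr: Sequence[float], n_levels: int = 6, max_pattern_length: int = 10
) -> float:
    """Regularity index from the corrected conditional entropy (in [0, 1]).

    The quantized series' conditional entropy CE(L) = E(L) - E(L-1) is
    corrected by adding ``perc(L) * E(1)`` where perc(L) is the fraction of
    length-L patterns observed only once (which biases raw CE toward zero).
    Regularity is ``1 - min_L CCE(L) / E(1)``: 1 for a perfectly predictable
    series, near 0 for white noise.  A zero-range series has Ro = 1 by
    convention.
    """
    sym = quantize_series(rr, n_levels)
    if sym.size < max_pattern_length + 1:
        max_pattern_length = max(2, sym.size - 1)
    e1, _ = _pattern_entropy(sym, 1)
    if e1 == 0.0:
        return 1.0
    best = e1  # NCCE(1) = 1 by definition
    prev = e1
    for L in range(2, max_pattern_length + 1):
        eL, perc = _pattern_entropy(sym, L)
        cce = (eL - prev) + perc * e1
        best = min(best, cce)
        prev = eL
    return float(1.0 - best / e1)


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def compute_proxies(
    series: RRSeries,
    max_order: int = 16,
    min_order: int = 8,
    prsa_window: int = 10,
    prsa_smoothing: int = 2,
    n_levels: int = 6,
) -> dict[str, float]:
    """Compute the full 12-proxy vector for one subject-epoch series.

    Proxies that are undefined on the series (no PRSA anchors, empty
    spectral bands) come back as NaN; panel-level policy decides their fate.
    """
    rr = series.rr
    hr, rr_rms, rmssd = time_domain(rr)
    det = detrend_rr(rr)
    spec = fit_ar_spectrum(det, float(np.mean(rr)), max_order=max_order, min_order=min_order)
    tp, lfa, hfa, lfnu, hfnu = band_powers(spec)
    return {
        "HR": hr,
        "RR_RMS": rr_rms,
        "RR_TP": tp,
        "RR_LFa": lfa,
        "RR_HFa": hfa,
        "RR_LFnu": lfnu,
        "RR_HFnu": hfnu,
        "RMSSD": rmssd,
        "AC": prsa(rr, "acceleration", prsa_window, prsa_smoothing),
        "DC": prsa(rr, "deceleration", prsa_window, prsa_smoothing),
        "RR_Ro": regularity_ro(rr, n_levels),
        "P0v": symbolic_p0v(rr, n_levels),
    }


def compute_proxy_panel(
    series_collection: Iterable[RRSeries],
    n_epochs: int = 9,
    missing: Literal["error", "impute", "drop"] = "error",
    **proxy_kwargs,
) -> pd.DataFrame:
    """Assemble the subject x epoch x 12-proxy long panel.

    Every subject must contribute all ``n_epochs`` epochs.  ``missing``
    controls undefined proxies: ``"error"`` (default) raises, ``"impute"``
    fills each proxy column with its median, ``"drop"`` removes affected
    subjects entirely (keeping the panel balanced).
    """
    rows = []
    for s in series_collection:
        rec = {"subject": s.subject_id, "group": s.group, "epoch": s.epoch_index}
        rec.update(compute_proxies(s, **proxy_kwargs))
        rows.append(rec)
    panel = pd.DataFrame(rows).sort_values(["subject", "epoch"]).reset_index(drop=True)

    counts = panel.groupby("subject")["epoch"].nunique()
    bad = counts[counts != n_epochs]
    if len(bad):
        raise ValueError(
            f"incomplete subjects (expected {n_epochs} epochs): "
            + ", ".join(f"{s} ({c})" for s, c in bad.items())
        )

    na_mask = panel[list(PROXY_NAMES)].isna()
    if na_mask.any().any():
        if missing == "error":
            where = panel.loc[na_mask.any(axis=1), ["subject", "epoch"]]
            raise ValueError(
                "undefined proxies at: "
                + "; ".join(f"{r.subject}/ep{r.epoch}" for r in where.itertuples())
            )
        if missing == "impute":
            for c in PROXY_NAMES:
                panel[c] = panel[c].fillna(panel[c].median())
        elif missing == "drop":
            bad_subjects = panel.loc[na_mask.any(axis=1), "subject"].unique()
            panel = panel[~panel["subject"].isin(bad_subjects)].reset_index(drop=True)
        else:
            raise ValueError(f"unknown missing-policy {missing!r}")
    return panel


def read_tachograms(path: str | Path) -> list[RRSeries]:
    """Read a tachogram CSV (columns subject, group, epoch, rr_ms)."""
    df = pd.read_csv(path)
    out = []
    for (subj, grp, ep), g in df.groupby(["subject", "group", "epoch"], sort=True):
        out.append(RRSeries(str(subj), str(grp), int(ep), g["rr_ms"].to_numpy()))
    return out


def write_spectrum_diagnostics(specs: dict[tuple, ARSpectrum], path: str | Path) -> None:
    """Dump per-epoch AR diagnostics (order, whiteness, components) as JSON."""
    payload = {
        f"{subj}/ep{ep}": {
            "order": sp.order,
            "whiteness_ok": sp.whiteness_ok,
            "n_components": len(sp.components),
            "total_power": sp.total_power,
        }
        for (subj, ep), sp in specs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
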