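"""Synthetic tachograms and proxy panels with controlled statistical structure.

Two generators cover the two entry points of the pipeline:

* :func:`generate_study` produces RR-interval series for a two-group,
  nine-epoch protocol.  Each epoch is the sum of a mean RR level, two
  narrow-band beat-domain AR(2) oscillators with spectral peaks at the LF and
  HF center frequencies (scaled to requested band powers), and white noise.
  The default template emulates a rest / stand / incremental exercise / peak
  / recovery protocol for endurance-trained (cyclist-like) vs. technical
  (shooter-like) athletes: spectral powers collapse toward zero at peak
  exercise (epoch 7), LF normalized power rises through the early exercise
  steps and falls toward the peak, and per-study beat counts land near
  1800 beats per subject.

* :func:`generate_proxy_panel` draws a subject x epoch x 12-variable panel
  directly from a two-level orthogonal factor model: a between-subject part
  (loadings times subject factor draws plus subject-level uniqueness noise)
  plus a within-subject part (loadings times epoch factor draws plus
  epoch-level noise), with standard-normal factors independent across
  levels.  This gives the factor-analysis stage a known ground truth.

Reproducibility uses a counter-based scheme: one global seed expands to
per-subject-epoch ``numpy.random.SeedSequence((seed, subject, epoch))``
streams, so any subset of the study regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from hrvmefa.proxies import PROXY_NAMES, RRSeries

__all__ = [
    "EpochProfile",
    "StudyConfig",
    "LatentPanelSpec",
    "generate_rr_epoch",
    "generate_study",
    "generate_proxy_panel",
    "default_study_config",
    "default_panel_spec",
    "write_tachogram_csv",
    "write_panel_csv",
    "study_config_to_yaml",
    "study_config_from_yaml",
]

_OSC_POLE_RADIUS = 0.95  # AR(2) pole radius; 0.9-0.97 keeps peaks narrow but proper


@dataclass
class EpochProfile:
    """Spectral recipe for one protocol epoch."""

    epoch_index: int
    mean_rr: float          # ms
    lf_power: float         # ms^2 at lf_center
    hf_power: float         # ms^2 at hf_center
    lf_center: float = 0.10  # Hz
    hf_center: float = 0.25  # Hz
    noise_sd: float = 3.0    # ms, white
    n_beats: int = 256
    vlf_wander_sd: float = 0.0  # ms, slow (~0.015 Hz) baseline wander amplitude

    def __post_init__(self) -> None:
        if not 1 <= self.epoch_index <= 9:
            raise ValueError("epoch_index must be 1-9")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.lf_power < 0 or self.hf_power < 0 or self.noise_sd < 0:
            raise ValueError("powers and noise must be nonnegative")
        if not (0.03 < self.lf_center < 0.15 <= self.hf_center <= 0.40):
            raise ValueError("band centers must satisfy 0.03 < LF < 0.15 <= HF <= 0.40")
        if self.n_beats < 64:
            raise ValueError("n_beats must be >= 64 for spectral analysis")


@dataclass
class StudyConfig:
    """A two-group protocol: per-group lists of nine epoch profiles."""

    n_per_group: int
    group_labels: tuple[str, str]
    profiles: dict[str, list[EpochProfile]]
    seed: int = 0
    subject_rr_cv: float = 0.05     # between-subject spread of mean RR
    subject_power_sd: float = 0.45  # lognormal sigma on overall spectral power
    band_power_sd: float = 0.35     # extra subject-level sigma per band (LF/HF)
    epoch_power_sd: float = 0.5     # epoch-level lognormal jitter on band powers
    epoch_rr_cv: float = 0.03       # epoch-level jitter on mean RR

    def __post_init__(self) -> None:
        if len(self.group_labels) != 2:
            raise ValueError("exactly two groups are supported")
        for g in self.group_labels:
            profs = self.profiles.get(g)
            if profs is None or len(profs) != 9:
                raise ValueError(f"group {g!r} needs exactly 9 epoch profiles")


@dataclass
class LatentPanelSpec:
    """Two-level factor model from which proxy panels are drawn.

    Per variable and level, communality (row sum of squared loadings) plus
    uniqueness must equal 1, so each level contributes unit variance.
    """

    n_subjects: int
    n_epochs: int
    bs_loadings: np.ndarray   # p x qB
    ws_loadings: np.ndarray   # p x qW
    uniquenesses_bs: np.ndarray
    uniquenesses_ws: np.ndarray
    group_shift: np.ndarray   # length qB, added to group-2 subjects' BS factors
    seed: int = 0
    variable_names: tuple[str, ...] = PROXY_NAMES
    group_labels: tuple[str, str] = ("cyclist", "shooter")

    def __post_init__(self) -> None:
        self.bs_loadings = np.atleast_2d(np.asarray(self.bs_loadings, dtype=float))
        self.ws_loadings = np.atleast_2d(np.asarray(self.ws_loadings, dtype=float))
        self.uniquenesses_bs = np.asarray(self.uniquenesses_bs, dtype=float)
        self.uniquenesses_ws = np.asarray(self.uniquenesses_ws, dtype=float)
        self.group_shift = np.asarray(self.group_shift, dtype=float)
        p = len(self.variable_names)
        if self.bs_loadings.shape[0] != p or self.ws_loadings.shape[0] != p:
            raise ValueError(f"loading matrices must have p = {p} rows")
        if self.bs_loadings.shape[1] < 1 or self.ws_loadings.shape[1] < 1:
            raise ValueError("at least one factor per level")
        for lam, psi, lvl in (
            (self.bs_loadings, self.uniquenesses_bs, "BS"),
            (self.ws_loadings, self.uniquenesses_ws, "WS"),
        ):
            comm = (lam**2).sum(axis=1)
            if np.any(np.abs(comm + psi - 1.0) > 1e-8):
                raise ValueError(f"{lvl} communality + uniqueness must equal 1 per variable")
        if self.group_shift.shape != (self.bs_loadings.shape[1],):
            raise ValueError("group_shift must have length qB")


# ---------------------------------------------------------------------------
# RR-series generation
# ---------------------------------------------------------------------------

def _ar2_oscillator(
    rng: np.random.Generator, n: int, f_beat: float, power: float,
    radius: float = _OSC_POLE_RADIUS, burn: int = 200,
) -> np.ndarray:
    """Narrow-band AR(2) process with peak at ``f_beat`` cycles/beat and
    stationary variance ``power``."""
    if power <= 0:
        return np.zeros(n)
    a1 = 2.0 * radius * np.cos(2.0 * np.pi * f_beat)
    a2 = -(radius**2)
    # stationary variance of AR(2): (1 - a2) s2 / ((1 + a2)((1 - a2)^2 - a1^2))
    gain = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1**2))
    s2 = power / gain
    # skewed (standardized gamma) innovations: real tachograms are
    # time-irreversible (heart-rate asymmetry), Gaussian AR processes are not
    k = 4.0
    eps = (rng.gamma(k, 1.0, n + burn) - k) / np.sqrt(k) * np.sqrt(s2)
    x = np.zeros(n + burn)
    for t in range(2, n + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + eps[t]
    return x[burn:]


def generate_rr_epoch(
    profile: EpochProfile,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S01",
    group: str = "A",
    max_retries: int = 10,
) -> RRSeries:
    """One epoch's tachogram: mean RR + LF and HF AR(2) oscillators + noise.

    Oscillator frequencies are interpreted on the beat axis via the epoch's
    mean RR (``f_beat = f_hz * mean_rr / 1000``).  A draw containing a
    non-positive RR interval is rejected wholesale and redrawn (truncation
    would distort the spectrum); persistently extreme parameters raise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    beat_s = profile.mean_rr / 1000.0
    for attempt, child in enumerate(ss.spawn(max_retries)):
        rng = np.random.default_rng(child)
        rr = np.full(profile.n_beats, profile.mean_rr, dtype=float)
        rr += _ar2_oscillator(rng, profile.n_beats, profile.lf_center * beat_s, profile.lf_power)
        rr += _ar2_oscillator(rng, profile.n_beats, profile.hf_center * beat_s, profile.hf_power)
        if profile.vlf_wander_sd > 0:
            # slow baseline wander below the LF band edge plus a random
            # linear drift: power that RR_RMS sees but the LF/HF bands do not
            t = np.arange(profile.n_beats, dtype=float)
            amp = abs(rng.normal(0.0, profile.vlf_wander_sd))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            f_vlf = 0.015 * beat_s  # cycles/beat
            rr += amp * np.sqrt(2.0) * np.sin(2.0 * np.pi * f_vlf * t + phase)
            slope = rng.normal(0.0, 2.0 * profile.vlf_wander_sd / profile.n_beats)
            rr += slope * (t - t.mean())
        if profile.noise_sd > 0:
            rr += rng.normal(0.0, profile.noise_sd, profile.n_beats)
        if np.all(rr > 0):
            return RRSeries(subject_id, group, profile.epoch_index, rr)
    raise ValueError(
        f"could not draw a positive tachogram for epoch {profile.epoch_index} "
        f"(mean_rr={profile.mean_rr}, powers too extreme?)"
    )


def _scaled_profile(
    p: EpochProfile,
    rr_factor: float,
    lf_factor: float,
    hf_factor: float,
    noise_factor: float = 1.0,
    wander_factor: float = 1.0,
    lf_center: float | None = None,
    hf_center: float | None = None,
) -> EpochProfile:
    amp = np.sqrt((lf_factor + hf_factor) / 2.0)
    return EpochProfile(
        epoch_index=p.epoch_index,
        mean_rr=p.mean_rr * rr_factor,
        lf_power=p.lf_power * lf_factor,
        hf_power=p.hf_power * hf_factor,
        lf_center=lf_center if lf_center is not None else p.lf_center,
        hf_center=hf_center if hf_center is not None else p.hf_center,
        noise_sd=p.noise_sd * noise_factor,
        n_beats=p.n_beats,
        vlf_wander_sd=p.vlf_wander_sd * amp * wander_factor,
    )


def generate_study(config: StudyConfig) -> list[RRSeries]:
    """Generate the full study: 2 groups x n_per_group subjects x 9 epochs.

    Subjects within a group share the group's epoch template but receive an
    individual mean-RR factor, an individual overall spectral-power factor
    and band-specific (LF/HF) factors -- this is the between-subject
    variance the two-level analysis decomposes.  On top of that each epoch's
    band powers and mean RR get multiplicative jitter, which gives the
    within-subject level its own stochastic variation beyond the epoch
    template.
    """
    out: list[RRSeries] = []
    for gi, g in enumerate(config.group_labels):
        for k in range(config.n_per_group):
            subj_idx = gi * config.n_per_group + k
            subj_id = f"{g[:3].upper()}{k + 1:02d}"
            srng = np.random.default_rng(
                np.random.SeedSequence((config.seed, subj_idx, 9999))
            )
            rr_factor = float(np.exp(srng.normal(0.0, config.subject_rr_cv)))
            pw = srng.normal(0.0, config.subject_power_sd)
            lf_subj = float(np.exp(pw + srng.normal(0.0, config.band_power_sd)))
            hf_subj = float(np.exp(pw + srng.normal(0.0, config.band_power_sd)))
            # independent subject traits that decorrelate the proxies:
            # baseline-wander load, short-term noise, oscillator frequencies
            wander_subj = float(np.exp(srng.normal(0.0, 0.5)))
            noise_subj = float(np.exp(srng.normal(0.0, 0.4)))
            lf_center = float(srng.uniform(0.08, 0.12))
            hf_center = float(srng.uniform(0.20, 0.32))
            for prof in config.profiles[g]:
                jrng = np.random.default_rng(
                    np.random.SeedSequence((config.seed, subj_idx, prof.epoch_index, 1))
                )
                lf_f = lf_subj * float(np.exp(jrng.normal(0.0, config.epoch_power_sd)))
                hf_f = hf_subj * float(np.exp(jrng.normal(0.0, config.epoch_power_sd)))
                rr_f = rr_factor * float(np.exp(jrng.normal(0.0, config.epoch_rr_cv)))
                ss = np.random.SeedSequence((config.seed, subj_idx, prof.epoch_index))
                out.append(
                    generate_rr_epoch(
                        _scaled_profile(
                            prof, rr_f, lf_f, hf_f,
                            noise_factor=noise_subj, wander_factor=wander_subj,
                            lf_center=lf_center, hf_center=hf_center,
                        ),
                        ss, subject_id=subj_id, group=g,
                    )
                )
    return out


# Per-epoch template: (mean_rr ms, LF ms^2, HF ms^2, n_beats, VLF wander ms).
# Encodes the protocol's ordinal trends: amplitude collapsing into peak
# exercise (epoch 7), LF share rising through the early steps then falling,
# partial recovery.
_BASE_EPOCHS = [
    (1, 950.0, 500.0, 600.0, 220, 20.0),   # rest
    (2, 820.0, 800.0, 200.0, 250, 16.0),   # stand
    (3, 700.0, 400.0, 80.0, 130, 10.0),    # exercise step 1
    (4, 600.0, 200.0, 40.0, 150, 7.0),     # exercise step 2
    (5, 480.0, 40.0, 12.0, 200, 4.0),      # exercise step 3
    (6, 400.0, 10.0, 5.0, 240, 2.5),       # exercise step 4
    (7, 340.0, 2.0, 1.5, 180, 2.0),        # peak
    (8, 480.0, 60.0, 40.0, 250, 5.0),      # recovery 1
    (9, 600.0, 150.0, 120.0, 200, 8.0),    # recovery 2
]


def default_study_config(n_per_group: int = 15, seed: int = 0) -> StudyConfig:
    """Exercise-like two-group template (endurance vs. technical athletes).

    The endurance ("cyclist") group gets ~10% longer RR intervals, doubled
    spectral amplitudes and an HF-shifted balance; the technical ("shooter")
    group keeps the base template with its LF-dominant balance.
    """
    def mk(rows, rr_f, lf_f, hf_f):
        return [
            EpochProfile(
                epoch_index=e, mean_rr=rr * rr_f, lf_power=lf * lf_f,
                hf_power=hf * hf_f, noise_sd=3.0, n_beats=nb,
                vlf_wander_sd=w * np.sqrt((lf_f + hf_f) / 2.0),
            )
            for e, rr, lf, hf, nb, w in rows
        ]

    profiles = {
        "cyclist": mk(_BASE_EPOCHS, 1.10, 1.5, 3.0),
        "shooter": mk(_BASE_EPOCHS, 1.00, 1.0, 1.0),
    }
    return StudyConfig(
        n_per_group=n_per_group,
        group_labels=("cyclist", "shooter"),
        profiles=profiles,
        seed=seed,
    )


def null_study_config(n_per_group: int = 15, seed: int = 0) -> StudyConfig:
    """Both groups share identical profiles (for calibration experiments)."""
    cfg = default_study_config(n_per_group, seed)
    cfg.profiles["cyclist"] = cfg.profiles["shooter"]
    return cfg


# ---------------------------------------------------------------------------
# Latent-panel generation
# ---------------------------------------------------------------------------

def generate_proxy_panel(spec: LatentPanelSpec) -> pd.DataFrame:
    """Draw a proxy panel from the two-level orthogonal factor model.

    ``X_ijt = bs_loadings @ f_i + e_i + ws_loadings @ g_it + eps_it`` with
    standard-normal factors, subject-level uniqueness noise ``e_i`` and
    epoch-level noise ``eps_it``; ``group_shift`` displaces the BS factor
    means of the second group.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    n, T = spec.n_subjects, spec.n_epochs
    p, qB = spec.bs_loadings.shape
    qW = spec.ws_loadings.shape[1]

    f = rng.standard_normal((n, qB))
    half = n // 2
    f[half:] += spec.group_shift
    e_subj = rng.standard_normal((n, p)) * np.sqrt(spec.uniquenesses_bs)
    between = f @ spec.bs_loadings.T + e_subj            # n x p

    g = rng.standard_normal((n, T, qW))
    eps = rng.standard_normal((n, T, p)) * np.sqrt(spec.uniquenesses_ws)
    within = g @ spec.ws_loadings.T + eps                # n x T x p

    X = between[:, None, :] + within
    rows = []
    for i in range(n):
        grp = spec.group_labels[0] if i < half else spec.group_labels[1]
        sid = f"{grp[:3].upper()}{(i % half) + 1:02d}" if half else f"S{i + 1:02d}"
        for t in range(T):
            rec = {"subject": sid, "group": grp, "epoch": t + 1}
            rec.update(dict(zip(spec.variable_names, X[i, t])))
            rows.append(rec)
    return pd.DataFrame(rows)


def _simple_structure(p: int, assignments: dict[int, list[int]], main: float,
                      signs: dict[tuple[int, int], float] | None = None) -> np.ndarray:
    lam = np.zeros((p, len(assignments)))
    for q, vars_ in assignments.items():
        for v in vars_:
            s = 1.0
            if signs and (v, q) in signs:
                s = signs[(v, q)]
            lam[v, q] = s * main
    return lam


def default_panel_spec(
    n_subjects: int = 30,
    n_epochs: int = 9,
    seed: int = 0,
    main_loading: float = 0.85,
    doublet_loading: float = 0.95,
) -> LatentPanelSpec:
    """Study-like two-level structure: q_B = 2, q_W = 3.

    Between level: an amplitude factor on the eight time-based variables
    (negative on HR and AC, echoing the inverse heart-rate and
    acceleration-capacity conventions) and a frequency factor on the four
    ratio-based variables (negative on RR_HFnu).  Within level: amplitude,
    signal-self-similarity (RR_Ro, P0v) and oscillatory (RR_LFnu vs.
    RR_HFnu, opposite signs) factors.  The two-indicator WS factors carry
    high marker loadings (0.95, as such doublets typically do when they are
    real) and small cross-loadings; every uniqueness stays <= 0.4.
    """
    names = PROXY_NAMES
    iv = {nm: i for i, nm in enumerate(names)}
    time_based = [iv[n] for n in ("HR", "RR_RMS", "RR_TP", "RR_LFa", "RR_HFa", "RMSSD", "AC", "DC")]
    ratio = [iv[n] for n in ("RR_LFnu", "RR_HFnu", "RR_Ro", "P0v")]

    bs = _simple_structure(
        12, {0: time_based, 1: ratio}, main_loading,
        signs={(iv["AC"], 0): -1.0, (iv["HR"], 0): -1.0, (iv["RR_HFnu"], 1): -1.0},
    )
    ws = _simple_structure(
        12,
        {0: time_based, 1: [iv["RR_Ro"], iv["P0v"]], 2: [iv["RR_LFnu"], iv["RR_HFnu"]]},
        doublet_loading,
        signs={(iv["AC"], 0): -1.0, (iv["HR"], 0): -1.0, (iv["RR_HFnu"], 2): -1.0},
    )
    for v in time_based:
        ws[v, 0] = np.sign(ws[v, 0]) * main_loading
    # Small cross-loadings anchor the two-indicator factors (a pure doublet
    # leaves its communalities unidentified and invites Heywood drift).
    cross = 0.15
    for v in ratio:
        ws[v, 0] = cross if v != iv["RR_HFnu"] else -cross
    ws[iv["RR_LFnu"], 1] = cross
    ws[iv["RR_HFnu"], 1] = -cross
    ws[iv["RR_Ro"], 2] = cross
    ws[iv["P0v"], 2] = cross
    psi_bs = 1.0 - (bs**2).sum(axis=1)
    psi_ws = 1.0 - (ws**2).sum(axis=1)
    return LatentPanelSpec(
        n_subjects=n_subjects,
        n_epochs=n_epochs,
        bs_loadings=bs,
        ws_loadings=ws,
        uniquenesses_bs=psi_bs,
        uniquenesses_ws=psi_ws,
        group_shift=np.array([1.0, -1.0]),
        seed=seed,
    )


def synthetic_demographics(
    subjects: Sequence[str], groups: Sequence[str], seed: int = 0
) -> pd.DataFrame:
    """Sex and age covariates, independent of the autonomic indicators.

    Drawn per subject (sex 0 = female, 1 = male with a 1/3 female share;
    age normal around 29 +- 6 years, clipped to 18-45), deterministically
    from the seed.  Being independent of the generated physiology, these
    covariates carry no true effect: they exercise the sex/age screen under
    its null.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 777)))
    n = len(subjects)
    sex = (rng.random(n) > 1.0 / 3.0).astype(int)
    age = np.clip(rng.normal(29.0, 6.0, n), 18.0, 45.0).round(1)
    return pd.DataFrame({"subject": list(subjects), "group": list(groups),
                         "sex": sex, "age": age})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_tachogram_csv(series: Sequence[RRSeries], path: str | Path) -> None:
    """Long CSV, one record per beat: subject, group, epoch, rr_ms."""
    frames = [
        pd.DataFrame(
            {"subject": s.subject_id, "group": s.group, "epoch": s.epoch_index, "rr_ms": s.rr}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def study_config_to_yaml(config: StudyConfig, path: str | Path) -> None:
    doc = {
        "n_per_group": config.n_per_group,
        "group_labels": list(config.group_labels),
        "seed": config.seed,
        "subject_rr_cv": config.subject_rr_cv,
        "subject_power_sd": config.subject_power_sd,
        "profiles": {
            g: [
                {
                    "epoch_index": int(p.epoch_index), "mean_rr": float(p.mean_rr),
                    "lf_power": float(p.lf_power), "hf_power": float(p.hf_power),
                    "lf_center": float(p.lf_center), "hf_center": float(p.hf_center),
                    "noise_sd": float(p.noise_sd), "n_beats": int(p.n_beats),
                    "vlf_wander_sd": float(p.vlf_wander_sd),
                }
                for p in profs
            ]
            for g, profs in config.profiles.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def study_config_from_yaml(path: str | Path) -> StudyConfig:
    doc = yaml.safe_load(Path(path).read_text())
    profiles = {
        g: [EpochProfile(**row) for row in rows] for g, rows in doc["profiles"].items()
    }
    return StudyConfig(
        n_per_group=doc["n_per_group"],
        group_labels=tuple(doc["group_labels"]),
        profiles=profiles,
        seed=doc.get("seed", 0),
        subject_rr_cv=doc.get("subject_rr_cv", 0.05),
        subject_power_sd=doc.get("subject_power_sd", 0.45),
    )
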