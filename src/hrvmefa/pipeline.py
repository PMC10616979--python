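"""End-to-end pipeline: simulate -> proxies -> MEFA -> inference -> report.

Each stage writes its numeric artifacts (CSV/JSON) into the output
directory; the reporting stage renders figures from those same tables.  A
manifest records package/library versions, the seed and input hashes, so a
run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hrvmefa import __version__
from hrvmefa.inference import (
    ALPHA,
    ats_longitudinal,
    ba_density_test,
    epoch_pair_trends,
    fdr_adjust,
    jt_test,
    ks_bootstrap_test,
    sensitivity_scores,
    sexage_screen,
    stwrs_test,
)
from hrvmefa.mefa import MefaConfig, MefaResult, fit_mefa
from hrvmefa.proxies import PROXY_NAMES, compute_proxy_panel
from hrvmefa.reporting import (
    autonomic_heatmap,
    group_summaries,
    hr_percent_of_max,
    median_profile_plot,
    median_profile_table,
    ws_subject_ranges,
)
from hrvmefa.resampling import bootstrap_mefa, make_plan
from hrvmefa.synthetic import (
    default_study_config,
    generate_study,
    study_config_to_yaml,
    synthetic_demographics,
    write_tachogram_csv,
)

__all__ = ["PipelineConfig", "run_all", "simulate_stage", "proxy_stage",
           "mefa_stage", "inference_stage", "report_stage"]


@dataclass
class PipelineConfig:
    n_per_group: int = 15
    seed: int = 0
    n_bootstrap: int = 300
    n_permutations: int = 1000
    with_jackknife: bool = False
    write_tachograms: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def simulate_stage(cfg: PipelineConfig, out: Path) -> list:
    study = default_study_config(n_per_group=cfg.n_per_group, seed=cfg.seed)
    series = generate_study(study)
    study_config_to_yaml(study, out / "study_config.yaml")
    if cfg.write_tachograms:
        write_tachogram_csv(series, out / "tachograms.csv")
    return series


def proxy_stage(series: list, out: Path) -> pd.DataFrame:
    panel = compute_proxy_panel(series)
    panel.to_csv(out / "proxy_panel.csv", index=False)
    return panel


def _loading_table(sol) -> pd.DataFrame:
    df = sol.to_frame().drop(columns="communality")
    footer = pd.DataFrame(
        [sol.variance_pct, sol.cumulative_pct, sol.communality_share_pct,
         np.cumsum(sol.communality_share_pct)],
        index=["% of total variance", "cumulative % of total variance",
               "% of total communality", "cumulative % of total communality"],
        columns=df.columns,
    )
    return pd.concat([df, footer])


def mefa_stage(panel: pd.DataFrame, cfg: PipelineConfig, out: Path) -> MefaResult:
    res = fit_mefa(panel)
    _loading_table(res.bs_solution).to_csv(out / "loadings_bs.csv")
    _loading_table(res.ws_solution).to_csv(out / "loadings_ws.csv")
    res.indicators.bs_scores.to_csv(out / "indicators_bs.csv", index=False)
    res.indicators.ws_scores.to_csv(out / "indicators_ws.csv", index=False)
    report = {
        "kmo_bs": res.correlations.kmo_b,
        "kmo_ws": res.correlations.kmo_w,
        "q_bs": res.bs_solution.q,
        "q_ws": res.ws_solution.q,
        "bs_labels": list(res.bs_solution.labels),
        "ws_labels": list(res.ws_solution.labels),
        "bs_heywood": res.bs_solution.heywood,
        "ws_heywood": res.ws_solution.heywood,
        "bs_rationale": res.bs_rationale,
        "ws_rationale": res.ws_rationale,
        "total_communality_bs": res.bs_solution.total_communality,
        "total_communality_ws": res.ws_solution.total_communality,
    }
    (out / "mefa_report.json").write_text(json.dumps(report, indent=1, default=float))
    return res


def inference_stage(
    panel: pd.DataFrame, res: MefaResult, cfg: PipelineConfig, out: Path,
):
    """Run the full test battery and assemble the sensitivity report.

    Emits a tidy ``inference.csv`` (one row per indicator/aspect/contrast/
    method) and ``sensitivity.json``.  Also bootstrap summaries
    (``bootstrap.json``) used for the confidence-interval procedures.
    """
    rows = []
    bs = res.indicators.bs_scores
    ws = res.indicators.ws_scores
    bs_names = list(bs.columns[2:])
    ws_names = list(ws.columns[3:])
    groups = sorted(bs["group"].unique())
    seed = cfg.seed

    # --- bootstrap of the factor solution and indicator medians
    plan = make_plan(bs.set_index("subject")["group"], B=cfg.n_bootstrap,
                     seed=seed + 1)
    boot = bootstrap_mefa(panel, plan, res, with_jackknife=cfg.with_jackknife)
    boot_doc = {
        "B": boot.B, "n_retained": boot.n_retained,
        "n_heywood": boot.n_heywood, "n_unmatched": boot.n_unmatched,
        "kmo_bs_ci": [boot.kmo_b.ci_low, boot.kmo_b.ci_high],
        "kmo_ws_ci": [boot.kmo_w.ci_low, boot.kmo_w.ci_high],
        "bs_variance_pct_ci": [list(np.atleast_1d(boot.bs_variance_pct.ci_low)),
                               list(np.atleast_1d(boot.bs_variance_pct.ci_high))],
        "ws_variance_pct_ci": [list(np.atleast_1d(boot.ws_variance_pct.ci_low)),
                               list(np.atleast_1d(boot.ws_variance_pct.ci_high))],
    }
    (out / "bootstrap.json").write_text(json.dumps(boot_doc, indent=1, default=float))

    def ci_nonoverlap(ind, ep) -> bool:
        tab = boot.ws_epoch_group_medians[ind]
        g = tab[tab["scope"] == "group"]
        try:
            iv = [
                (g.loc[[(grp, ep)]]["ci_low"].iloc[0], g.loc[[(grp, ep)]]["ci_high"].iloc[0])
                for grp in groups
            ]
        except KeyError:
            return False
        return iv[0][1] < iv[1][0] or iv[1][1] < iv[0][0]

    def ci_pair_nonoverlap(ind, e0, e1) -> bool:
        tab = boot.ws_epoch_group_medians[ind]
        a = tab[tab["scope"] == "all"]
        try:
            lo0, hi0 = a.loc[e0, "ci_low"], a.loc[e0, "ci_high"]
            lo1, hi1 = a.loc[e1, "ci_low"], a.loc[e1, "ci_high"]
        except KeyError:
            return False
        return hi0 < lo1 or hi1 < lo0

    # --- ATS on every proxy and WS indicator (group / epoch / interaction)
    for col, frame, kind in (
        [(c, panel, "proxy") for c in PROXY_NAMES]
        + [(c, ws, "ws-indicator") for c in ws_names]
    ):
        ats = ats_longitudinal(frame, col)
        for eff, r in (("group", ats.group_effect), ("epoch", ats.epoch_effect),
                       ("interaction", ats.interaction)):
            rows.append({"indicator": col, "kind": kind, "aspect": "longitudinal",
                         "contrast": eff, "method": "ATS", "statistic": r.statistic,
                         "p": r.p_value, "p_adj": np.nan,
                         "significant": r.p_value <= ALPHA})

    # --- BS indicators: group comparisons
    for col in bs_names:
        x = bs.loc[bs["group"] == groups[0], col].to_numpy()
        y = bs.loc[bs["group"] == groups[1], col].to_numpy()
        for fn, nm in ((ba_density_test, "BA"), (ks_bootstrap_test, "KS-boot"),
                       (stwrs_test, "StWRS")):
            r = fn(x, y, cfg.n_permutations, seed)
            rows.append({"indicator": col, "kind": "bs-indicator", "aspect": "group",
                         "contrast": "overall", "method": nm, "statistic": r.statistic,
                         "p": r.p_value, "p_adj": np.nan, "significant": r.p_value <= ALPHA})
        r = jt_test([x, y], cfg.n_permutations, seed)
        rows.append({"indicator": col, "kind": "bs-indicator", "aspect": "group",
                     "contrast": "overall", "method": "JT", "statistic": r.statistic,
                     "p": r.p_value, "p_adj": np.nan, "significant": r.p_value <= ALPHA})

    # --- WS indicators: per-epoch group comparisons with FDR per family
    epoch_rows = []
    for col in ws_names:
        for ep in sorted(ws["epoch"].unique()):
            sub = ws[ws["epoch"] == ep]
            x = sub.loc[sub["group"] == groups[0], col].to_numpy()
            y = sub.loc[sub["group"] == groups[1], col].to_numpy()
            for fn, nm in ((ba_density_test, "BA"), (ks_bootstrap_test, "KS-boot"),
                           (stwrs_test, "StWRS")):
                r = fn(x, y, cfg.n_permutations, seed + ep)
                epoch_rows.append({"indicator": col, "kind": "ws-indicator",
                                   "aspect": "group-by-epoch", "contrast": f"ep{ep}",
                                   "method": nm, "statistic": r.statistic, "p": r.p_value})
            r = jt_test([x, y], cfg.n_permutations, seed + ep)
            epoch_rows.append({"indicator": col, "kind": "ws-indicator",
                               "aspect": "group-by-epoch", "contrast": f"ep{ep}",
                               "method": "JT", "statistic": r.statistic, "p": r.p_value})
    epoch_df = pd.DataFrame(epoch_rows)
    epoch_df["p_adj"] = np.nan
    for (col, nm), mask in epoch_df.groupby(["indicator", "method"]).groups.items():
        epoch_df.loc[mask, "p_adj"] = fdr_adjust(epoch_df.loc[mask, "p"].to_numpy())
    epoch_df["significant"] = epoch_df["p_adj"] <= ALPHA
    rows.extend(epoch_df.to_dict("records"))

    # --- consecutive-epoch trends per WS indicator
    trend_frames = {}
    for col in ws_names:
        tr = epoch_pair_trends(ws, col, n_permutations=cfg.n_permutations, seed=seed)
        trend_frames[col] = tr
        for _, r in tr.iterrows():
            rows.append({"indicator": col, "kind": "ws-indicator", "aspect": "trend",
                         "contrast": r["pair"], "method": r["method"],
                         "statistic": r["statistic"], "p": r["p"],
                         "p_adj": r["p_adj"], "significant": bool(r["significant"])})

    # --- sex/age screen (BS overall; WS per epoch)
    demo = synthetic_demographics(bs["subject"], bs["group"], seed=seed)
    screen_rows = []
    for col in bs_names:
        terms = sexage_screen(bs[col], demo["sex"], demo["age"])
        for term, r in terms.items():
            screen_rows.append({"indicator": col, "kind": "bs-indicator",
                                "aspect": "sex-age", "contrast": term,
                                "method": r.method, "statistic": r.statistic,
                                "p": r.p_value, "p_adj": np.nan,
                                "significant": r.p_value <= ALPHA})
    for col in ws_names:
        for ep in sorted(ws["epoch"].unique()):
            sub = ws[ws["epoch"] == ep].merge(demo, on=["subject", "group"])
            terms = sexage_screen(sub[col], sub["sex"], sub["age"])
            for term, r in terms.items():
                screen_rows.append({"indicator": col, "kind": "ws-indicator",
                                    "aspect": "sex-age", "contrast": f"ep{ep}:{term}",
                                    "method": r.method, "statistic": r.statistic,
                                    "p": r.p_value, "p_adj": np.nan,
                                    "significant": r.p_value <= ALPHA})
    rows.extend(screen_rows)

    inference_df = pd.DataFrame(rows)
    inference_df.to_csv(out / "inference.csv", index=False)

    # --- sensitivity battery per WS indicator
    battery = {}
    ats_results = {
        col: ats_longitudinal(ws, col) for col in ws_names
    }
    for col in ws_names:
        tr = trend_frames[col]

        def pair_sig(pair, method):
            m = tr[(tr["pair"] == pair) & (tr["method"] == method)]
            return bool(m["significant"].iloc[0]) if len(m) else False

        rest_stand = {
            "ATS": pair_sig("1-2", "ATS"),
            "WSR": pair_sig("1-2", "WSR"),
            "bootstrap-CI": ci_pair_nonoverlap(col, 1, 2),
        }
        exercise = {}
        for t0 in range(2, 9):
            pair = f"{t0}-{t0 + 1}"
            exercise[pair] = {
                "ATS": pair_sig(pair, "ATS"),
                "WSR": pair_sig(pair, "WSR"),
                "bootstrap-CI": ci_pair_nonoverlap(col, t0, t0 + 1),
            }
        ats_r = ats_results[col]
        overall = {
            "ATS-group": ats_r.group_effect.p_value <= ALPHA,
            "ATS-interaction": ats_r.interaction.p_value <= ALPHA,
        }
        epochs = {}
        sub = epoch_df[epoch_df["indicator"] == col]
        for ep in sorted(ws["epoch"].unique()):
            procs = {
                r["method"]: bool(r["significant"])
                for _, r in sub[sub["contrast"] == f"ep{ep}"].iterrows()
            }
            procs["bootstrap-CI"] = ci_nonoverlap(col, ep)
            epochs[f"ep{ep}"] = procs
        battery[col] = {
            "rest-stand": rest_stand,
            "exercise-fraction": exercise,
            "sports-specialties": {"overall": overall, "epochs": epochs},
        }
    report = sensitivity_scores(battery)
    (out / "sensitivity.json").write_text(json.dumps(report.to_dict(), indent=1, default=str))
    return inference_df, report, boot, trend_frames


def report_stage(panel, res: MefaResult, boot, trend_frames, out: Path) -> list[str]:
    figures = []
    ws = res.indicators.ws_scores
    bs = res.indicators.bs_scores
    ws_names = list(ws.columns[3:])
    bs_names = list(bs.columns[2:])

    hr_ind, hr_sum = hr_percent_of_max(panel)
    hr_ind.to_csv(out / "hr_percent_individual.csv", index=False)
    hr_sum.to_csv(out / "hr_percent_summary.csv", index=False)

    for c in PROXY_NAMES:
        median_profile_table(panel, c, by_group=True).to_csv(
            out / f"profile_{c}.csv", index=False)
    fig = out / "profiles_proxies.png"
    _proxy_grid(panel, fig)
    figures.append(str(fig))

    for col in ws_names:
        ci = None
        if col in boot.ws_epoch_group_medians:
            tab = boot.ws_epoch_group_medians[col]
            ci = tab[tab["scope"] == "all"][["ci_low", "ci_high"]]
        path = out / f"profile_{col}.png"
        tbl = median_profile_plot(
            ws, col, path, ci_table=ci, by_group=True,
            annotations=trend_frames.get(col), title=col,
        )
        tbl.to_csv(out / f"profile_{col}.csv", index=False)
        figures.append(str(path))

    # BS indicator group summaries
    summ = pd.concat(
        [group_summaries(bs, c).assign(indicator=c) for c in bs_names]
    )
    summ.to_csv(out / "bs_group_summaries.csv", index=False)

    # heatmaps: pair each BS indicator with related-meaning WS indicators
    def short(name):
        return name.split("-")[0]

    pairs = []
    for b in bs_names:
        mates = [w for w in ws_names if short(w) == short(b)]
        if not mates and short(b) == "FRE":
            mates = [w for w in ws_names if short(w) in ("SSS", "OSC")]
        for w in mates or ws_names[:1]:
            pairs.append((b, w))
    for b, w in pairs:
        png = out / f"heatmap_{short(b)}_{short(w)}.png"
        html = out / f"heatmap_{short(b)}_{short(w)}.html"
        mat = autonomic_heatmap(bs, ws, b, w, png, html)
        mat.to_csv(out / f"heatmap_{short(b)}_{short(w)}.csv")
        figures += [str(png), str(html)]
    return figures


def _proxy_grid(panel: pd.DataFrame, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 4, figsize=(14, 8), sharex=True)
    for ax, c in zip(axes.ravel(), PROXY_NAMES):
        for g, color in zip(sorted(panel["group"].unique()), ("tab:blue", "tab:red")):
            t = median_profile_table(panel[panel["group"] == g], c)
            ax.errorbar(t["epoch"], t["median"], yerr=t["MAD"], marker="o",
                        ms=3, capsize=2, color=color, label=g)
        ax.set_title(c, fontsize=9)
    axes[0, 0].legend(fontsize=7, frameon=False)
    for ax in axes[-1]:
        ax.set_xlabel("epoch")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def run_all(outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Run the whole pipeline into ``outdir`` and return a result manifest."""
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = simulate_stage(cfg, out)
        panel = proxy_stage(series, out)
        res = mefa_stage(panel, cfg, out)
        inference_df, sens, boot, trends = inference_stage(panel, res, cfg, out)
        figures = report_stage(panel, res, boot, trends, out)

    manifest = {
        "hrvmefa": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "n_per_group": cfg.n_per_group,
        "n_bootstrap": cfg.n_bootstrap,
        "n_permutations": cfg.n_permutations,
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "panel": panel, "mefa": res, "inference": inference_df,
        "sensitivity": sens, "bootstrap": boot, "figures": figures,
        "manifest": manifest,
    }
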