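"""Summary statistics, median-profile plots and autonomic heatmap plots.

Every figure has a numeric twin: the plotting functions consume plain
DataFrames that the pipeline also writes as CSV, so a figure is a pure
function of its table.  MAD is the raw median absolute deviation from the
median (no 1.4826 consistency factor).
"""

from __future__ import annotations

import html as _html
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "mad",
    "hr_percent_of_max",
    "group_summaries",
    "ws_subject_ranges",
    "median_profile_table",
    "median_profile_plot",
    "autonomic_heatmap",
]


def mad(x) -> float:
    """Median absolute deviation from the median, unscaled."""
    x = np.asarray(x, float)
    return float(np.median(np.abs(x - np.median(x))))


def hr_percent_of_max(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject percentages of maximal heart rate and a group summary.

    ``HR.t% = 100 * HR.t / HRmax`` with HRmax the subject's maximum over
    the epochs (reached at peak exercise).  Returns ``(individual, summary)``
    where ``summary`` has mean/sd/median/MAD rows per group and epoch.
    """
    if panel["HR"].isna().any():
        raise ValueError("missing HR values")
    df = panel[["subject", "group", "epoch", "HR"]].copy()
    hrmax = df.groupby("subject")["HR"].transform("max")
    df["hr_pct"] = 100.0 * df["HR"] / hrmax
    peak = df.loc[df.groupby("subject")["HR"].idxmax(), ["subject", "epoch"]]
    df = df.merge(peak.rename(columns={"epoch": "peak_epoch"}), on="subject")

    rows = []
    for (grp, ep), g in df.groupby(["group", "epoch"]):
        v = g["hr_pct"]
        rows.append({
            "group": grp, "epoch": ep, "mean": v.mean(), "sd": v.std(ddof=1),
            "median": v.median(), "MAD": mad(v),
        })
    return df, pd.DataFrame(rows)


def group_summaries(scores: pd.DataFrame, value_col: str, group_col: str = "group") -> pd.DataFrame:
    """Median, MAD, min, max and range of an indicator per group."""
    rows = []
    for grp, g in scores.groupby(group_col):
        v = g[value_col].to_numpy()
        if v.size == 0:
            raise ValueError(f"empty group {grp!r}")
        rows.append({
            "group": grp, "median": float(np.median(v)), "MAD": mad(v),
            "min": float(v.min()), "max": float(v.max()),
            "range": float(v.max() - v.min()), "n": int(v.size),
        })
    return pd.DataFrame(rows)


def ws_subject_ranges(ws_scores: pd.DataFrame, value_col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject range over epochs and its min/median/max per group."""
    per_subj = (
        ws_scores.groupby(["group", "subject"])[value_col]
        .agg(lambda v: v.max() - v.min())
        .rename("range")
        .reset_index()
    )
    summary = (
        per_subj.groupby("group")["range"].agg(["min", "median", "max"]).reset_index()
    )
    return per_subj, summary


def median_profile_table(
    ws_values: pd.DataFrame, value_col: str, by_group: bool = False
) -> pd.DataFrame:
    keys = ["group", "epoch"] if by_group else ["epoch"]
    out = (
        ws_values.groupby(keys)[value_col]
        .agg(median="median", MAD=mad)
        .reset_index()
    )
    return out


def median_profile_plot(
    ws_values: pd.DataFrame,
    value_col: str,
    path: str | Path,
    ci_table: pd.DataFrame | None = None,
    by_group: bool = True,
    annotations: pd.DataFrame | None = None,
    title: str | None = None,
) -> pd.DataFrame:
    """Median profile over the nine epochs with MAD or bootstrap-CI bars.

    ``ci_table`` (optional) must be indexed by epoch with ``ci_low`` /
    ``ci_high`` columns; without it the error bars are +-MAD.
    ``annotations`` may carry consecutive-pair significance marks (columns
    ``pair`` and ``significant``); missing annotations only produce a plot
    without marks.
    """
    table = median_profile_table(ws_values, value_col, by_group=by_group)
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = table["group"].unique() if by_group else [None]
    colors = {g: c for g, c in zip(groups, ("tab:blue", "tab:red", "tab:green"))}
    for g in groups:
        sub = table[table["group"] == g] if g is not None else table
        x = sub["epoch"].to_numpy()
        med = sub["median"].to_numpy()
        if ci_table is not None and g is None:
            lo = ci_table.reindex(x)["ci_low"].to_numpy()
            hi = ci_table.reindex(x)["ci_high"].to_numpy()
            yerr = np.vstack([med - lo, hi - med])
        else:
            yerr = sub["MAD"].to_numpy()
        ax.errorbar(x, med, yerr=yerr, marker="o", capsize=3,
                    label=str(g) if g is not None else "all",
                    color=colors.get(g, "tab:gray"))
    if annotations is not None and {"pair", "significant"} <= set(annotations.columns):
        ymax = ax.get_ylim()[1]
        for _, row in annotations[annotations["significant"]].iterrows():
            t0 = int(str(row["pair"]).split("-")[0])
            ax.text(t0 + 0.5, ymax, "*", ha="center", va="top", fontsize=12)
    ax.set_xlabel("epoch")
    ax.set_ylabel(value_col)
    ax.set_xticks(sorted(ws_values["epoch"].unique()))
    if by_group:
        ax.legend(frameon=False)
    ax.set_title(title or value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return table


# ---------------------------------------------------------------------------
# Autonomic heatmap
# ---------------------------------------------------------------------------

def _heatmap_matrix(
    bs_scores: pd.DataFrame, ws_scores: pd.DataFrame, bs_col: str, ws_col: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rows = subjects ordered by ascending BS score within group; columns =
    the BS indicator followed by the 9 WS epochs."""
    if set(bs_scores["subject"]) != set(ws_scores["subject"]):
        missing = set(bs_scores["subject"]) ^ set(ws_scores["subject"])
        raise ValueError(f"subject keys differ between BS and WS tables: {sorted(missing)}")
    wide = ws_scores.pivot_table(index="subject", columns="epoch", values=ws_col)
    bs = bs_scores.set_index("subject")
    # tie-break on subject id for a reproducible ordering
    order = bs.sort_index(kind="stable").sort_values(bs_col, kind="stable")
    mat = pd.concat([order[[bs_col]], wide.reindex(order.index)], axis=1)
    meta = order[["group", bs_col]]
    return mat, meta


def autonomic_heatmap(
    bs_scores: pd.DataFrame,
    ws_scores: pd.DataFrame,
    bs_col: str,
    ws_col: str,
    path_png: str | Path,
    path_html: str | Path | None = None,
    cmaps: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-block autonomic heatmap: one BS column plus 9 WS epoch columns.

    Subjects are ordered by ascending BS indicator score within their
    group; cell tonality increases monotonically with the [0, 100] score.
    The right margin carries the group summaries (median +- MAD, min, max,
    range for the BS indicator; min/median/max per-subject WS ranges).  An
    optional standalone HTML export embeds the unencoded scores cell by
    cell (shown on hover and printed in-cell).
    """
    mat, meta = _heatmap_matrix(bs_scores, ws_scores, bs_col, ws_col)
    groups = list(dict.fromkeys(bs_scores["group"]))
    cmaps = cmaps or {groups[0]: "Blues", groups[1]: "YlOrBr"}

    bs_sum = group_summaries(bs_scores, bs_col)
    _, ws_rng = ws_subject_ranges(ws_scores, ws_col)

    fig, axes = plt.subplots(
        len(groups), 1, figsize=(9, 0.32 * len(mat) + 2.0), squeeze=False,
        gridspec_kw={"height_ratios": [np.sum(meta["group"] == g) for g in groups]},
    )
    for gi, g in enumerate(groups):
        ax = axes[gi, 0]
        rows = meta["group"] == g
        block = mat[rows.to_numpy()]
        im = ax.imshow(
            block.to_numpy(), cmap=cmaps.get(g, "viridis"), vmin=0, vmax=100,
            aspect="auto", interpolation="nearest",
        )
        ax.set_yticks(range(len(block)))
        ax.set_yticklabels(block.index, fontsize=7)
        ax.set_xticks(range(block.shape[1]))
        ax.set_xticklabels([bs_col] + [f"ep{c}" for c in mat.columns[1:]],
                           fontsize=7, rotation=45, ha="right")
        srow = bs_sum[bs_sum["group"] == g].iloc[0]
        rrow = ws_rng[ws_rng["group"] == g].iloc[0]
        ax.set_title(
            f"{g}:  {bs_col} {srow['median']:.1f}±{srow['MAD']:.1f} "
            f"[{srow['min']:.1f}, {srow['max']:.1f}] range {srow['range']:.1f} | "
            f"{ws_col} ranges {rrow['min']:.1f}/{rrow['median']:.1f}/{rrow['max']:.1f}",
            fontsize=8, loc="left",
        )
        fig.colorbar(im, ax=ax, fraction=0.02)
    fig.suptitle(f"{bs_col} + {ws_col}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path_png, dpi=150)
    plt.close(fig)

    if path_html is not None:
        _write_heatmap_html(mat, meta, bs_col, ws_col, groups, Path(path_html))
    return mat


def _css_color(value: float, warm: bool) -> str:
    """Monotone single-hue tonality for a [0, 100] score."""
    t = np.clip(value / 100.0, 0, 1)
    if warm:
        r, g, b = 255, int(235 - 150 * t), int(205 - 190 * t)
    else:
        r, g, b = int(230 - 190 * t), int(240 - 160 * t), 255
    return f"rgb({r},{g},{b})"


def _write_heatmap_html(mat, meta, bs_col, ws_col, groups, path: Path) -> None:
    rows_html = []
    for gi, g in enumerate(groups):
        rows_html.append(
            f"<tr><th colspan='{mat.shape[1] + 1}' style='text-align:left'>{_html.escape(str(g))}</th></tr>"
        )
        for subj in meta.index[meta['group'] == g]:
            cells = [f"<th>{_html.escape(str(subj))}</th>"]
            for col, val in mat.loc[subj].items():
                color = _css_color(float(val), warm=(gi == 1))
                label = bs_col if col == bs_col else f"epoch {col}"
                cells.append(
                    f"<td style='background:{color}' title='{_html.escape(str(subj))} "
                    f"{_html.escape(str(label))}: {val:.2f}'>{val:.1f}</td>"
                )
            rows_html.append("<tr>" + "".join(cells) + "</tr>")
    header = "".join(
        f"<th>{_html.escape(bs_col if c == bs_col else f'ep{c}')}</th>" for c in mat.columns
    )
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{_html.escape(bs_col)} + {_html.escape(ws_col)}</title>
<style>
table {{ border-collapse: collapse; font: 11px sans-serif; }}
td, th {{ border: 1px solid #ccc; padding: 2px 6px; text-align: right; }}
td:hover {{ outline: 2px solid #333; cursor: default; }}
</style></head><body>
<h3>Autonomic heatmap: {_html.escape(bs_col)} + {_html.escape(ws_col)}</h3>
<p>Rows are subjects ordered by ascending {_html.escape(bs_col)} score within group;
hover a cell for the unencoded score.</p>
<table><tr><th>subject</th>{header}</tr>
{''.join(rows_html)}
</table></body></html>
"""
    path.write_text(doc)
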