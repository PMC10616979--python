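#!/usr/bin/env python
"""Profiles, group summaries and autonomic heatmap plots.

Renders the per-proxy median profile grid, the WS-indicator median
profiles with bootstrap confidence bands, the group summary tables, and
the two-block autonomic heatmaps (static PNG plus standalone HTML with
unencoded scores on hover).  Every figure is drawn from a CSV twin written
next to it.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from hrvmefa.pipeline import PipelineConfig, mefa_stage, report_stage
from hrvmefa.resampling import bootstrap_mefa, make_plan


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-bootstrap", type=int, default=300)
    args = ap.parse_args()

    panel = pd.read_csv(args.out / "proxy_panel.csv")
    cfg = PipelineConfig(seed=args.seed, n_bootstrap=args.n_bootstrap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mefa_stage(panel, cfg, args.out)
        plan = make_plan(
            res.indicators.bs_scores.set_index("subject")["group"],
            B=cfg.n_bootstrap, seed=args.seed + 1,
        )
        boot = bootstrap_mefa(panel, plan, res, with_jackknife=False)
        figures = report_stage(panel, res, boot, {}, args.out)

    print(f"wrote {len(figures)} figures:")
    for f in figures:
        print(" ", f)


if __name__ == "__main__":
    main()
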