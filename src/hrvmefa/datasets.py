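"""Worked-example reference tables.

Rotated two-level factor loadings from a published athlete study of the
same 12-proxy protocol (30 elite athletes, two training groups, nine
epochs): a 12 x 2 between-subject solution (amplitude + frequency domains)
and a 12 x 3 within-subject solution (amplitude, signal self-similarity,
oscillatory).  They serve as worked-example inputs for the variance /
communality accounting and the factor-labeling rules; the underlying raw
recordings are not public, so these printed matrices are the only numeric
anchor available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "bs_reference_loadings",
    "ws_reference_loadings",
    "BS_REFERENCE_SUMMARY",
    "WS_REFERENCE_SUMMARY",
]

# Between-subject solution: rows in the source table's own order.
_BS_ROWS = [
    # variable,   factor 1, factor 2
    ("RR_RMS",  0.867, -0.405),
    ("RR_TP",   0.840, -0.290),
    ("RR_LFa",  0.681,  0.031),
    ("RR_HFa",  0.654, -0.275),
    ("RMSSD",   0.854, -0.380),
    ("AC",     -0.760,  0.231),
    ("DC",      0.752, -0.068),
    ("HR",     -0.494,  0.559),
    ("RR_LFnu", -0.185,  0.707),
    ("RR_HFnu",  0.340, -0.708),
    ("RR_Ro",  -0.229,  0.915),
    ("P0v",     0.014,  0.904),
]

# Within-subject solution.
_WS_ROWS = [
    ("HR",     -0.810,  0.149, -0.105),
    ("RR_RMS",  0.857,  0.189,  0.005),
    ("RR_TP",   0.854, -0.107, -0.248),
    ("RR_LFa",  0.723, -0.034,  0.131),
    ("RR_HFa",  0.603, -0.156, -0.442),
    ("RMSSD",   0.914, -0.257, -0.123),
    ("AC",     -0.856,  0.271, -0.011),
    ("DC",      0.829, -0.203,  0.022),
    ("RR_Ro",  -0.153,  0.953,  0.041),
    ("P0v",    -0.150,  0.962,  0.110),
    ("RR_LFnu", 0.355,  0.091,  0.782),
    ("RR_HFnu", 0.199, -0.027, -0.761),
]

#: Printed summary rows of the between-subject solution.
BS_REFERENCE_SUMMARY = {
    "variance_pct": (38.89, 29.12),
    "cumulative_pct": (38.89, 68.01),
    "communality_share_pct": (57.18, 42.82),
    "total_communality": 8.161,
}

#: Printed summary rows of the within-subject solution.
WS_REFERENCE_SUMMARY = {
    "variance_pct": (45.62, 17.66, 12.55),
    "cumulative_pct": (45.62, 63.28, 75.83),
    "communality_share_pct": (60.16, 23.29, 16.55),
    "total_communality": 9.099,
}


def bs_reference_loadings() -> pd.DataFrame:
    """12 x 2 rotated between-subject loading matrix (worked example)."""
    df = pd.DataFrame(_BS_ROWS, columns=["variable", "BS factor 1", "BS factor 2"])
    return df.set_index("variable")


def ws_reference_loadings() -> pd.DataFrame:
    """12 x 3 rotated within-subject loading matrix (worked example)."""
    df = pd.DataFrame(
        _WS_ROWS,
        columns=["variable", "WS factor 1", "WS factor 2", "WS factor 3"],
    )
    return df.set_index("variable")
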