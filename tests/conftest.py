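import warnings

import numpy as np
import pandas as pd
import pytest

from hrvmefa.synthetic import (
    LatentPanelSpec,
    default_panel_spec,
    default_study_config,
    generate_proxy_panel,
    generate_study,
)


@pytest.fixture(autouse=True)
def _quiet():
    """The factoring stages warn liberally (KMO, smoothing); keep logs clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def latent_panel():
    """One study-sized panel drawn from the known two-level factor model."""
    spec = default_panel_spec(seed=42)
    return spec, generate_proxy_panel(spec)


@pytest.fixture(scope="session")
def study_panel():
    """Proxy panel computed from a full synthetic tachogram study."""
    from hrvmefa.proxies import compute_proxy_panel

    series = generate_study(default_study_config(seed=0))
    return compute_proxy_panel(series)


@pytest.fixture
def toy_panel():
    """2 subjects x 2 epochs x 2 proxies with hand-checkable correlations."""
    rows = []
    data = {
        ("s1", 1): (1.0, 10.0), ("s1", 2): (3.0, 14.0),
        ("s2", 1): (2.0, 11.0), ("s2", 2): (8.0, 13.0),
    }
    for (subj, ep), (a, b) in data.items():
        rows.append({"subject": subj, "group": "g", "epoch": ep, "A": a, "B": b})
    return pd.DataFrame(rows)


def simple_structure_spec(
    n_subjects=30, n_epochs=9, seed=0, markers_per_factor=(4, 4, 4), main=0.85,
) -> LatentPanelSpec:
    """Panel spec without doublet factors (every factor >= 3 markers)."""
    p = 12
    q = len(markers_per_factor)
    lam = np.zeros((p, q))
    start = 0
    for k, m in enumerate(markers_per_factor):
        lam[start:start + m, k] = main
        start += m
    psi = 1.0 - (lam**2).sum(axis=1)
    return LatentPanelSpec(
        n_subjects=n_subjects, n_epochs=n_epochs,
        bs_loadings=lam[:, :2], ws_loadings=lam,
        uniquenesses_bs=1.0 - (lam[:, :2] ** 2).sum(axis=1),
        uniquenesses_ws=psi,
        group_shift=np.zeros(2), seed=seed,
    )
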