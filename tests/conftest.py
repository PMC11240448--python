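"""Shared fixtures: small synthetic cohorts and oracle networks."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cstar.preprocess import aggregate, batch_normalize, feature_matrix
from cstar.syndata import (
    DatasetSpec,
    DPD_NODES,
    MODULES,
    NODES,
    example_local_response,
    make_ground_truth,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def serum_cohort():
    """12-line serum-condition cohort (sigma=0.3): features + labels."""
    net = make_ground_truth("mTOR-driven", seed=5)
    spec = DatasetSpec(n_lines_per_class=4, sigma=0.3, seed=5)
    cells, truth = simulate_dataset(net, spec, conditions=["serum"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        markers = batch_normalize(aggregate(cells), spec.control_line)
    feats = feature_matrix(markers, exclude=(spec.control_line,))
    return feats, truth.labels.loc[feats.index]


@pytest.fixture(scope="session")
def oracle_r():
    """The fixed identifiable 6-module + 2-DPD local response matrix."""
    return example_local_response()


def perturbation_design(modules, strengths=(0.3, 0.6)):
    """Single-module inhibitor experiments; mTORi also hits both DPD nodes."""
    exps = []
    for m in modules:
        hit = [m] + (DPD_NODES if m == "mTOR_S6K" else [])
        for s in strengths:
            exps.append((f"{m}|{s}", {n: -s for n in hit}))
    return exps


@pytest.fixture(scope="session")
def chain_twin_setup():
    """3-module chain twin with known DPD force coefficients."""
    from cstar.twin import build_twin

    nodes = ["M1", "M2", "M3", "DPD_onc"]
    r = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for n in nodes:
        r.loc[n, n] = -1.0
    r.loc["M2", "M1"] = 0.7
    r.loc["M3", "M2"] = 0.6
    r.loc["DPD_onc", "M1"] = 0.6
    r.loc["DPD_onc", "M2"] = 0.5
    r.loc["DPD_onc", "M3"] = -0.4
    twin = build_twin(r, s_init={"DPD_onc": 0.2})
    return r, twin
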