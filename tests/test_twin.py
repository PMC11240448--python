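"""Twin dynamics: forces, equilibration, construction, fitting."""

import numpy as np
import pandas as pd
import pytest

from cstar.syndata import archetype_twin, make_ground_truth
from cstar.twin import (
    DPDDynamicsParams,
    DPDNode,
    TreatmentSpec,
    TwinModel,
    build_twin,
    equilibrate,
    fit_twin,
    restoring_force,
    signaling_betas,
    signaling_force,
    simulate,
)


# -- restoring force -------------------------------------------------------


def test_restoring_force_zeros_and_breakpoint_values():
    p = DPDDynamicsParams(alpha0=2.0, alpha1=2.0, s0=-1.0, s1=1.0)
    assert restoring_force(p.s0, p) == 0.0
    assert restoring_force(p.s1, p) == 0.0
    assert restoring_force(p.midpoint, p) == 0.0
    # barrier-side maximum at (s0 + 3 s1)/4: alpha1 (s1 - s0)/4
    assert restoring_force(0.5, p) == pytest.approx(1.0)


def test_restoring_force_continuous_at_breakpoints():
    p = DPDDynamicsParams(alpha0=1.3, alpha1=2.7, s0=-0.8, s1=1.4)
    for b in p.breakpoints:
        left = restoring_force(b - 1e-10, p)
        right = restoring_force(b + 1e-10, p)
        assert left == pytest.approx(right, abs=1e-8)
    # adjacent-branch algebra at (3 s0 + s1)/4: both give -alpha0 (s1-s0)/4
    b1 = p.breakpoints[0]
    assert restoring_force(b1, p) == pytest.approx(-p.alpha0 * (p.s1 - p.s0) / 4)


def test_dpd_params_validation():
    with pytest.raises(ValueError, match="s0 < s1"):
        DPDDynamicsParams(s0=1.0, s1=-1.0)
    with pytest.raises(ValueError, match="slopes"):
        DPDDynamicsParams(alpha0=-1.0)


# -- signaling force -------------------------------------------------------


def test_signaling_force_arithmetic():
    beta = signaling_betas({"m1": 0.5}, s_stst=2.0, x_stst={"m1": 1.0})
    assert beta == {"m1": 1.0}
    assert signaling_force(beta, {"m1": 1.0}) == pytest.approx(1.0)
    assert signaling_force({}, {}) == 0.0
    with pytest.raises(ValueError, match="zero steady-state"):
        signaling_betas({"m1": 0.5}, 2.0, {"m1": 0.0})


def test_signaling_force_at_steady_state_is_r_times_s():
    """With x_j = x_j^st.st each term reduces to r_Sj * S^st.st."""
    r_s = {"a": 0.4, "b": -0.3}
    x_st = {"a": 0.6, "b": 0.2}
    beta = signaling_betas(r_s, s_stst=1.5, x_stst=x_st)
    sigma = signaling_force(beta, x_st)
    assert sigma == pytest.approx(1.5 * (0.4 - 0.3))


# -- equilibration ---------------------------------------------------------


def test_equilibrate_closed_form_and_fixed_point():
    m = TwinModel(["M"], basal={"M": 0.2})
    y = equilibrate(m)
    kact, kdeact = m.rates["kact"], m.rates["kdeact"]
    expect = kact * 0.2 / (kact * 0.2 + kdeact)
    assert m.raw_activity(y, "M") == pytest.approx(expect, rel=1e-6)
    y2 = equilibrate(m, y0=y)
    assert np.allclose(y, y2, atol=1e-7)


def test_equilibrate_zero_drive_gives_zero_activity():
    m = TwinModel(["M"], basal={"M": 0.0})
    y = equilibrate(m)
    assert m.raw_activity(y, "M") == pytest.approx(0.0, abs=1e-8)


# -- construction ----------------------------------------------------------


def _r(nodes, edges):
    r = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for n in nodes:
        r.loc[n, n] = -1.0
    for (s, t), w in edges.items():
        r.loc[t, s] = w
    return r


def test_positive_edge_raises_target_steady_state():
    r = _r(["A", "B"], {("A", "B"): 0.8})
    twin = build_twin(r)
    low = twin.copy(); low.basal["A"] = 0.05
    high = twin.copy(); high.basal["A"] = 0.8
    b_low = low.raw_activity(equilibrate(low), "B")
    b_high = high.raw_activity(equilibrate(high), "B")
    assert b_high > b_low


def test_negative_edge_lowers_target_steady_state():
    r = _r(["A", "B"], {("A", "B"): -0.8})
    twin = build_twin(r)
    low = twin.copy(); low.basal["A"] = 0.05
    high = twin.copy(); high.basal["A"] = 0.8
    assert high.raw_activity(equilibrate(high), "B") < \
        low.raw_activity(equilibrate(low), "B")


def test_no_significant_edges_decouples_modules():
    r = _r(["A", "B"], {("A", "B"): 0.8})
    no_sig = pd.DataFrame(False, index=r.index, columns=r.columns)
    twin = build_twin(r, significant=no_sig)
    assert twin.edges == {}
    y = equilibrate(twin)
    kact, kdeact = twin.rates["kact"], twin.rates["kdeact"]
    basal_ss = kact * 0.2 / (kact * 0.2 + kdeact)
    for m in ("A", "B"):
        assert twin.raw_activity(y, m) == pytest.approx(basal_ss, rel=1e-6)


def test_erk_cascade_with_negative_feedback_is_built():
    net = make_ground_truth("mTOR-driven", seed=1)
    twin = archetype_twin(net)
    assert twin.mechanistic_erk
    assert {"SOS", "RAS", "RAF", "MEK", "ERK"} <= set(twin.state_names)
    # higher ERK activity accelerates SOS and RAF deactivation
    trt = TreatmentSpec(egf=1.0)
    y = equilibrate(twin, trt)
    idx = twin._index
    y_hi = y.copy(); y_hi[idx["ERK"]] = 0.9
    y_lo = y.copy(); y_lo[idx["ERK"]] = 0.0
    d_hi = twin.rhs(0.0, y_hi, trt)
    d_lo = twin.rhs(0.0, y_lo, trt)
    assert d_hi[idx["SOS"]] < d_lo[idx["SOS"]]
    assert d_hi[idx["RAF"]] < d_lo[idx["RAF"]]


def test_missing_dpd_in_edges_leaves_restoring_force_only():
    r = _r(["A", "DPD_onc"], {})
    twin = build_twin(r, s_init={"DPD_onc": 0.6})
    y = equilibrate(twin)
    assert twin.dpd_state(y, "DPD_onc") == pytest.approx(1.0, abs=1e-6)


# -- simulation ------------------------------------------------------------


def test_simulation_flat_at_fixed_point():
    net = make_ground_truth("mTOR-driven", seed=1)
    twin = archetype_twin(net)
    y0 = equilibrate(twin)
    res = simulate(twin, TreatmentSpec(egf=0.0), [0, 20, 60], y0=y0)
    assert np.allclose(res.states.iloc[0], res.states.iloc[-1], atol=1e-6)


def test_egf_step_converges_to_positive_oncogenic_state():
    net = make_ground_truth("mTOR-driven", seed=1)
    twin = archetype_twin(net)
    y0 = equilibrate(twin)
    res = simulate(twin, TreatmentSpec(egf=1.0), np.linspace(0, 400, 30),
                   y0=y0)
    s = res.dpd["DPD_onc"].to_numpy()
    assert (s > 0).all()
    y_eq = equilibrate(twin, TreatmentSpec(egf=1.0), y0=y0)
    assert s[-1] == pytest.approx(twin.dpd_state(y_eq, "DPD_onc"), abs=1e-3)
    # from below the steady state the score rises monotonically toward it
    y_low = y0.copy()
    y_low[twin._index["S_DPD_onc"]] = 0.2
    res2 = simulate(twin, TreatmentSpec(egf=1.0), np.linspace(0, 200, 20),
                    y0=y_low)
    s2 = res2.dpd["DPD_onc"].to_numpy()
    assert s2[1] > s2[0]                 # rises from the sub-steady start
    assert s2[-1] == pytest.approx(s[-1], rel=1e-3)


def test_state_fractions_stay_in_unit_interval():
    net = make_ground_truth("STAT3-driven", seed=2)
    twin = archetype_twin(net)
    y0 = equilibrate(twin)
    res = simulate(twin, TreatmentSpec(egf=1.0, doses={"EGFR": 4.0}),
                   np.linspace(0, 60, 20), y0=y0)
    frac_cols = [c for c in res.states.columns if not c.startswith("S_")]
    vals = res.states[frac_cols].to_numpy()
    assert vals.min() >= -1e-9 and vals.max() <= 1.0 + 1e-9


def test_dpd_bistability_under_zero_force():
    params = DPDDynamicsParams()
    twin = TwinModel([], dpd_nodes=[DPDNode("DPD_onc", params=params,
                                            s_init=0.3)])
    hi = equilibrate(twin)
    assert twin.dpd_state(hi, "DPD_onc") == pytest.approx(1.0, abs=1e-6)
    twin2 = TwinModel([], dpd_nodes=[DPDNode("DPD_onc", params=params,
                                             s_init=-0.3)])
    lo = equilibrate(twin2)
    assert twin2.dpd_state(lo, "DPD_onc") == pytest.approx(-1.0, abs=1e-6)


def test_treatment_validation():
    with pytest.raises(ValueError, match="EGF"):
        TreatmentSpec(egf=-1.0)
    with pytest.raises(ValueError, match="negative inhibitor"):
        TreatmentSpec(doses={"PKC": -2.0})


# -- fitting ---------------------------------------------------------------


def _fit_datasets(twin, noise=0.0, seed=0):
    t_grid = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 60.0])
    treatments = [TreatmentSpec(), TreatmentSpec(doses={"M1": 4.0}),
                  TreatmentSpec(doses={"M2": 4.0}),
                  TreatmentSpec(doses={"M3": 4.0})]
    y0 = equilibrate(twin)
    rng = np.random.default_rng(seed)
    out = []
    for trt in treatments:
        res = simulate(twin, trt, t_grid, y0=y0)
        obs = pd.concat([res.activities[["M1", "M2", "M3"]],
                         res.dpd[["DPD_onc"]]], axis=1)
        if noise:
            obs = obs * np.exp(rng.normal(0.0, noise, size=obs.shape))
        out.append((trt, t_grid, obs))
    return out


def test_self_fit_reaches_global_optimum(chain_twin_setup):
    _, truth = chain_twin_setup
    datasets = _fit_datasets(truth, noise=0.0)
    model = truth.copy()
    model.dpd_nodes[0].beta = {m: 0.0 for m in ["M1", "M2", "M3"]}
    bounds = {f"beta:DPD_onc:{m}": (-3.0, 3.0) for m in ["M1", "M2", "M3"]}
    fit = fit_twin(model, datasets, bounds, seed=1, n_runs=2, maxiter=25,
                   popsize=6)
    assert fit.objective < 1e-6
    true_beta = truth.dpd_nodes[0].beta
    for m, b in true_beta.items():
        assert fit.params[f"beta:DPD_onc:{m}"] == pytest.approx(b, abs=0.01)
    # the generative parameters are themselves a global optimum
    assert fit.objective <= 1e-6
    assert min(r["objective"] for r in fit.runs) == fit.objective


def test_fit_requires_finite_bounds(chain_twin_setup):
    _, truth = chain_twin_setup
    with pytest.raises(ValueError, match="bounds"):
        fit_twin(truth, [], {})
    with pytest.raises(ValueError, match="finite bounds"):
        fit_twin(truth, [], {"beta:DPD_onc:M1": (0.0, np.inf)})
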