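"""BMRA inference: oracle recovery, forward prediction, driver ranking."""

import numpy as np
import pandas as pd
import pytest

from cstar.netinfer import (
    BayesianMRA,
    cluster_driver_profiles,
    forward_predict,
    infer,
    linear_response_experiments,
    rank_drivers,
)
from cstar.responses import default_prior
from cstar.syndata import DPD_NODES, MODULES, NODES, make_ground_truth

from conftest import perturbation_design


def _two_node_inputs():
    r = pd.DataFrame([[-1.0, 0.0], [1.0, -1.0]],
                     index=["A", "B"], columns=["A", "B"])
    exps = [("A|0.5", {"A": -0.5}), ("B|0.5", {"B": -0.5}),
            ("A|0.25", {"A": -0.25})]
    R, P = linear_response_experiments(r, exps)
    return r, R, P


def test_two_node_chain_exact_recovery():
    r, R, P = _two_node_inputs()
    bmra = infer(R, P)
    assert abs(bmra.local_response_.loc["B", "A"] - 1.0) < 1e-6
    assert bmra.local_response_.loc["A", "B"] == 0.0
    assert np.allclose(np.diag(bmra.local_response_.to_numpy()), -1.0)


def test_forbidden_edges_have_zero_inclusion(oracle_r):
    R, P = linear_response_experiments(oracle_r, perturbation_design(MODULES))
    bmra = infer(R, P, default_prior(NODES))
    forb = bmra.inclusion_.loc[MODULES, DPD_NODES]
    assert (forb == 0.0).all().all()
    assert (bmra.local_response_.loc[MODULES, DPD_NODES] == 0.0).all().all()


def test_five_inhibitor_design_recovers_edge_signs(oracle_r):
    """Study-like design (no STAT3 perturbation): signs of strong edges."""
    five = [m for m in MODULES if m != "STAT3"]
    R, P = linear_response_experiments(oracle_r, perturbation_design(five))
    bmra = infer(R, P, default_prior(NODES))
    for tgt in NODES:
        for src in NODES:
            true = oracle_r.loc[tgt, src]
            if src != tgt and abs(true) > 0.1:
                est = bmra.local_response_.loc[tgt, src]
                assert np.sign(est) == np.sign(true), (src, tgt, true, est)


def test_full_design_recovers_magnitudes(oracle_r):
    R, P = linear_response_experiments(oracle_r, perturbation_design(MODULES))
    bmra = infer(R, P, default_prior(NODES))
    for tgt in NODES:
        for src in NODES:
            true = oracle_r.loc[tgt, src]
            if src != tgt and abs(true) > 0.1:
                est = bmra.local_response_.loc[tgt, src]
                assert abs(est - true) <= 1e-3 * max(1.0, abs(true))


def test_inverse_consistency_random_small_networks():
    """infer(generate(r)) == r for random sparse r, <= 6 nodes."""
    rng = np.random.default_rng(4)
    for trial in range(3):
        n = 5
        nodes = [f"N{i}" for i in range(n)]
        r = pd.DataFrame(-np.eye(n), index=nodes, columns=nodes)
        for tgt in range(n):
            srcs = rng.choice([s for s in range(n) if s != tgt], size=2,
                              replace=False)
            for s in srcs:
                r.iloc[tgt, s] = rng.uniform(0.3, 1.0) * rng.choice([-1, 1])
        exps = [(f"{m}|{s}", {m: -s}) for m in nodes for s in (0.3, 0.6)]
        R, P = linear_response_experiments(r, exps)
        bmra = infer(R, P)
        assert np.allclose(bmra.local_response_.to_numpy(), r.to_numpy(),
                           atol=1e-3)


def test_mra_constraint_violations_raise():
    r, R, P = _two_node_inputs()
    P_all = P.copy()
    P_all["B"] = 1  # every experiment now directly perturbs B
    with pytest.raises(ValueError, match="every experiment perturbs"):
        infer(R, P_all)


def test_underdetermined_without_prior_raises():
    nodes = [f"N{i}" for i in range(5)]
    r = pd.DataFrame(-np.eye(5), index=nodes, columns=nodes)
    R, P = linear_response_experiments(r, [("N0", {"N0": -0.5}),
                                           ("N1", {"N1": -0.5})])
    with pytest.raises(ValueError, match="prior"):
        infer(R, P)


def test_forward_prediction_hand_examples():
    r = pd.DataFrame([[-1.0, 0.0], [1.0, -1.0]],
                     index=["A", "B"], columns=["A", "B"])
    out = forward_predict(r, np.array([-0.5, 0.0]))
    assert np.allclose(out, [-0.5, -0.5], atol=1e-9)
    assert np.allclose(forward_predict(r, np.zeros(2)), 0.0)
    iso = pd.DataFrame(-np.eye(2), index=["A", "B"], columns=["A", "B"])
    assert np.allclose(forward_predict(iso, np.array([-0.5, 0.0])),
                       [-0.5, 0.0])


def test_forward_prediction_singular_matrix_errors():
    sing = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
    with pytest.raises(np.linalg.LinAlgError, match="condition number"):
        forward_predict(sing, np.array([1.0, 0.0]))


def test_forward_backward_round_trip(oracle_r):
    """forward_predict on the inferred r reproduces the measured columns."""
    exps = perturbation_design(MODULES)
    R, P = linear_response_experiments(oracle_r, exps)
    bmra = infer(R, P, default_prior(NODES))
    for name, hits in exps[:4]:
        r_p = pd.Series(0.0, index=NODES)
        for node, s in hits.items():
            r_p[node] = s
        pred = bmra.forward_predict(r_p)
        assert np.allclose(pred.to_numpy(), R[name].to_numpy(), atol=1e-3)


def test_rank_drivers_mtor_archetype(oracle_r):
    R, P = linear_response_experiments(oracle_r, perturbation_design(MODULES))
    bmra = infer(R, P, default_prior(NODES))
    ranking = rank_drivers(bmra, "DPD_onc")
    assert ranking.primary == "mTOR_S6K"
    assert not ranking.normal_weak
    with pytest.raises(ValueError, match="unknown DPD node"):
        rank_drivers(bmra, "DPD_x")


def test_rank_drivers_normal_weak_flag():
    """Sub-threshold edges drown in measurement noise: empty ranking."""
    net = make_ground_truth("normal-weak", seed=2)
    R, P = linear_response_experiments(net.r, perturbation_design(MODULES))
    rng = np.random.default_rng(0)
    R_noisy = R + rng.normal(0.0, 0.05, size=R.shape)
    bmra = infer(R_noisy, P, default_prior(NODES))
    ranking = rank_drivers(bmra, "DPD_onc")
    assert ranking.normal_weak and ranking.drivers == []


def test_rank_drivers_tie_breaks_by_global_influence():
    nodes = ["A", "B", "DPD_onc"]
    bmra = BayesianMRA()
    bmra.nodes_ = nodes
    r = pd.DataFrame(-np.eye(3), index=nodes, columns=nodes)
    r.loc["DPD_onc", "A"] = 0.5
    r.loc["DPD_onc", "B"] = 0.5
    r.loc["A", "B"] = 0.4  # B also acts through A: larger global influence
    bmra.local_response_ = r
    sig = pd.DataFrame(False, index=nodes, columns=nodes)
    sig.loc["DPD_onc", ["A", "B"]] = True
    bmra.significant_ = sig
    ranking = rank_drivers(bmra, "DPD_onc")
    assert [d[0] for d in ranking.drivers] == ["B", "A"]


def test_cluster_recovers_archetype_groups():
    rng = np.random.default_rng(1)
    centers = {"g1": [1.0, 0.1, 0.0, 0.0], "g2": [0.0, 1.0, 0.2, 0.0],
               "g3": [0.0, 0.0, 1.0, 0.3], "g4": [0.3, 0.0, 0.0, 1.0]}
    rows, truth = [], []
    for g, c in centers.items():
        for i in range(3):
            rows.append(np.array(c) + rng.normal(0, 0.05, 4))
            truth.append(g)
    profiles = pd.DataFrame(rows, index=[f"L{i}" for i in range(12)])
    labels, _ = cluster_driver_profiles(profiles, n_clusters=4)
    df = pd.DataFrame({"found": labels, "true": truth})
    # each found cluster maps to exactly one archetype and vice versa
    assert df.groupby("true")["found"].nunique().eq(1).all()
    assert df.groupby("found")["true"].nunique().eq(1).all()


def test_cluster_identical_rows_and_permutation_invariance():
    profiles = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
    labels, _ = cluster_driver_profiles(profiles, cut_height=0.1)
    assert labels.nunique() == 1
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
    l1, _ = cluster_driver_profiles(X, n_clusters=2)
    perm = list("fabcde")
    l2, _ = cluster_driver_profiles(X.loc[perm], n_clusters=2)
    # same partition regardless of row order
    for i in X.index:
        for j in X.index:
            assert (l1[i] == l1[j]) == (l2[i] == l2[j])
    with pytest.raises(ValueError, match="at least 2"):
        cluster_driver_profiles(X.iloc[:1])


def test_more_experiments_do_not_widen_credible_intervals():
    """Average CI width shrinks (or holds) as columns are added."""
    r, _, _ = _two_node_inputs()
    rng = np.random.default_rng(3)
    widths = {}
    for reps in (1, 4):
        exps = [(f"A|{i}", {"A": -0.5}) for i in range(reps)] + \
               [(f"B|{i}", {"B": -0.5}) for i in range(reps)]
        R, P = linear_response_experiments(r, exps)
        w = []
        for seed in range(5):
            noisy = R + np.random.default_rng(seed).normal(0, 0.1, R.shape)
            b = infer(noisy, P, random_state=seed)
            w.append(float(b.ci_high_.loc["B", "A"] - b.ci_low_.loc["B", "A"]))
        widths[reps] = np.mean(w)
    assert widths[4] <= widths[1]
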