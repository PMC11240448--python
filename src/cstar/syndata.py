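"""Synthetic mass-cytometry-like cohorts with known ground truth.

Emulates the structure of a multi-batch CYTOF perturbation screen over a
panel of breast cell lines: ~29 phospho-analytes, of which a subset read
out six core signaling modules (EGFR, PI3K/AKT, MEK/ERK, PKC, mTOR/S6K,
STAT3) and the rest are bystanders; serum-grown and serum-starved
EGF-stimulation time courses; five kinase-inhibitor perturbations; batches
of one or two lines, each carrying reference samples of a shared control
line; multiplicative lognormal single-cell noise and uniform per-batch
scale factors.

Each cell line is given a ground-truth core network drawn from one of five
driver archetypes.  Module activities and the two phenotype coordinates
(DPD_onc, DPD_LB) are simulated with the digital-twin ODE model, mapped to
analyte intensities, and sampled per cell.  The generative truth (edge
coefficients, DPD trajectories, analyte means) is exported alongside the
data so that recovery tests have an oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .twin import (
    DPDDynamicsParams,
    DPDNode,
    TreatmentSpec,
    TwinModel,
    build_twin,
    equilibrate,
    simulate,
)

__all__ = [
    "MODULES",
    "DPD_NODES",
    "DRIVER_CLASSES",
    "DEFAULT_PANEL",
    "MODULE_OUTPUTS",
    "DEFAULT_INHIBITORS",
    "GroundTruthNetwork",
    "DatasetSpec",
    "archetype_twin",
    "example_local_response",
    "TruthBundle",
    "make_ground_truth",
    "simulate_dataset",
    "export_truth",
    "load_truth",
]

MODULES = ["EGFR", "PI3K_AKT", "MEK_ERK", "PKC", "mTOR_S6K", "STAT3"]
DPD_NODES = ["DPD_onc", "DPD_LB"]
NODES = MODULES + DPD_NODES

DRIVER_CLASSES = ("mTOR-driven", "MEK-driven", "STAT3-driven", "PKC-driven",
                  "normal-weak")

#: analyte -> module readout map (None = bystander).  29 analytes.
DEFAULT_PANEL = {
    "pEGFR": "EGFR",
    "pAKT": "PI3K_AKT", "pGSK3B": "PI3K_AKT",
    "pERK": "MEK_ERK", "pMEK": "MEK_ERK", "pRSK": "MEK_ERK",
    "pPKCa": "PKC", "pMARCKS": "PKC",
    "pS6K": "mTOR_S6K", "pS6": "mTOR_S6K", "p4EBP1": "mTOR_S6K",
    "pSTAT3": "STAT3", "pSTAT3_S727": "STAT3",
    # bystanders
    "pMKK4": None, "pJNK": None, "pP38": None, "pCREB": None, "pNFkB": None,
    "pSMAD2": None, "pSRC": None, "pFAK": None, "pPLCg2": None, "pcJUN": None,
    "pSTAT5": None, "pP90RSK_S380": None, "pRB": None, "CyclinB1": None,
    "Ki67": None, "cPARP": None,
}

#: module -> representative output analyte (used for response matrices)
MODULE_OUTPUTS = {
    "EGFR": "pEGFR", "PI3K_AKT": "pAKT", "MEK_ERK": "pERK",
    "PKC": "pPKCa", "mTOR_S6K": "pS6", "STAT3": "pSTAT3",
}

#: inhibitor -> (target module, default dose in Kd units)
DEFAULT_INHIBITORS = {
    "EGFRi": ("EGFR", 4.0),
    "PI3Ki": ("PI3K_AKT", 4.0),
    "MEKi": ("MEK_ERK", 4.0),
    "PKCi": ("PKC", 4.0),
    "mTORi": ("mTOR_S6K", 4.0),
}

# signaling backbone shared by all archetypes
_BACKBONE = {
    ("EGFR", "PI3K_AKT"): 0.9,
    ("EGFR", "MEK_ERK"): 0.8,
    ("EGFR", "STAT3"): 0.6,
    ("PI3K_AKT", "mTOR_S6K"): 0.2,
    ("MEK_ERK", "EGFR"): 0.3,
}

# archetype-specific signaling edges and DPD in-edges.
# The negative DPD_onc in-edges make the oncogenic state signaling-maintained:
# without them the force sum_j beta_j x_j is non-negative and no inhibitor
# could ever destroy the oncogenic attractor of the piecewise-linear force.
_ARCHETYPES = {
    "mTOR-driven": {
        "signaling": {("mTOR_S6K", "PKC"): 1.2, ("PKC", "mTOR_S6K"): 1.2},
        "feedbacks": [("mTOR_S6K", "PKC"), ("PKC", "mTOR_S6K")],
        "dpd_onc": {"mTOR_S6K": 1.0, "PKC": 0.85, "MEK_ERK": 0.08,
                    "STAT3": -0.72, "PI3K_AKT": -0.45},
    },
    "MEK-driven": {
        "signaling": {("PI3K_AKT", "PKC"): 0.5},
        "feedbacks": [],
        "dpd_onc": {"MEK_ERK": 1.0, "PKC": 0.5, "mTOR_S6K": 0.3,
                    "STAT3": -0.6, "PI3K_AKT": -0.4},
    },
    "STAT3-driven": {
        "signaling": {("STAT3", "EGFR"): 0.5, ("PI3K_AKT", "PKC"): 0.6,
                      ("PKC", "STAT3"): 0.5},
        "feedbacks": [("STAT3", "EGFR")],
        "dpd_onc": {"STAT3": 1.0, "PKC": 0.6, "MEK_ERK": -0.5,
                    "PI3K_AKT": -0.35},
    },
    "PKC-driven": {
        "signaling": {("PI3K_AKT", "PKC"): 0.6, ("PKC", "mTOR_S6K"): 0.7},
        "feedbacks": [],
        "dpd_onc": {"PKC": 1.0, "mTOR_S6K": 0.5, "STAT3": -0.6,
                    "PI3K_AKT": -0.4},
    },
    "normal-weak": {
        "signaling": {},
        "feedbacks": [],
        "dpd_onc": {},  # filled with sub-threshold edges
    },
}

#: generator bound on DPD_onc in-edges of the normal-weak archetype
NORMAL_WEAK_BOUND = 0.05

# DPD_LB in-edges (applied to every archetype; STAT3 maintains the luminal
# side, MEK/ERK pushes basal)
_DPD_LB_EDGES = {"STAT3": -0.8, "MEK_ERK": 0.4}


def example_local_response() -> pd.DataFrame:
    """A fixed, hand-specified core network for validation and demos.

    Six signaling modules plus the two DPD nodes, diagonal -1, no DPD
    out-edges.  The parent sets are chosen so that every edge is
    identifiable from single-module perturbations: no module's response
    vector is an exact linear combination of another candidate's on the
    experiments that constrain any given target.
    """
    r = pd.DataFrame(0.0, index=NODES, columns=NODES)
    for n in NODES:
        r.loc[n, n] = -1.0
    edges = {
        ("EGFR", "PI3K_AKT"): 0.8,
        ("EGFR", "MEK_ERK"): 0.7,
        ("EGFR", "STAT3"): 0.6,
        ("PI3K_AKT", "mTOR_S6K"): 0.6,
        ("MEK_ERK", "mTOR_S6K"): 0.5,
        ("mTOR_S6K", "PKC"): 0.8,
        ("MEK_ERK", "EGFR"): 0.3,
        ("mTOR_S6K", "DPD_onc"): 0.9,
        ("PKC", "DPD_onc"): 0.5,
        ("STAT3", "DPD_onc"): -0.4,
        ("STAT3", "DPD_LB"): -0.7,
        ("MEK_ERK", "DPD_LB"): 0.35,
    }
    for (src, tgt), w in edges.items():
        r.loc[tgt, src] = w
    return r


@dataclass
class GroundTruthNetwork:
    """A known core network: 6 signaling modules + 2 DPD nodes.

    ``r`` is the local response matrix (row = target, column = source) with
    the diagonal convention ``r_ii = -1`` and no outgoing edges from DPD
    nodes.
    """

    driver_class: str
    r: pd.DataFrame
    feedbacks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        r = self.r
        if list(r.index) != NODES or list(r.columns) != NODES:
            raise ValueError("network matrix must be indexed by the 8 default nodes")
        if not np.allclose(np.diag(r.to_numpy()), -1.0):
            raise ValueError("diagonal convention r_ii = -1 violated")
        off = r.loc[:, DPD_NODES].drop(index=DPD_NODES, errors="ignore")
        if not (off == 0).all().all():
            raise ValueError("DPD nodes must have no outgoing edges")
        onc = r.loc["DPD_onc", MODULES].abs()
        if self.driver_class == "normal-weak":
            if (onc > NORMAL_WEAK_BOUND).any():
                raise ValueError("normal-weak archetype exceeds the edge bound")
        else:
            driver = _DRIVER_MODULE[self.driver_class]
            if onc.idxmax() != driver:
                raise ValueError(
                    f"{self.driver_class}: largest DPD_onc in-edge is "
                    f"{onc.idxmax()}, expected {driver}"
                )

    @property
    def modules(self) -> list:
        return list(MODULES)

    def edge(self, source: str, target: str) -> float:
        return float(self.r.loc[target, source])


_DRIVER_MODULE = {
    "mTOR-driven": "mTOR_S6K",
    "MEK-driven": "MEK_ERK",
    "STAT3-driven": "STAT3",
    "PKC-driven": "PKC",
}


def make_ground_truth(driver_class: str, seed: int = 0,
                      jitter: float = 0.08) -> GroundTruthNetwork:
    """Generate a ground-truth core network for one driver archetype.

    The named driver carries the largest-magnitude edge into ``DPD_onc``;
    the ``normal-weak`` archetype has all DPD_onc in-edges below
    :data:`NORMAL_WEAK_BOUND`.  Edges are multiplicatively jittered
    (uniform ``1 +- jitter``) with a seeded generator, so identical seeds
    give identical networks.
    """
    if driver_class not in DRIVER_CLASSES:
        raise ValueError(
            f"unknown driver_class {driver_class!r}; expected one of {DRIVER_CLASSES}"
        )
    rng = np.random.default_rng(seed)
    arch = _ARCHETYPES[driver_class]
    r = pd.DataFrame(0.0, index=NODES, columns=NODES)
    np.fill_diagonal(r.to_numpy(), 0.0)
    for i in NODES:
        r.loc[i, i] = -1.0

    def put(target, source, value):
        r.loc[target, source] = value * rng.uniform(1 - jitter, 1 + jitter)

    for (src, tgt), w in _BACKBONE.items():
        put(tgt, src, w)
    for (src, tgt), w in arch["signaling"].items():
        put(tgt, src, w)

    if driver_class == "normal-weak":
        for m in MODULES:
            mag = rng.uniform(0.2, 0.8) * NORMAL_WEAK_BOUND
            r.loc["DPD_onc", m] = mag * rng.choice([-1.0, 1.0])
        for m, w in _DPD_LB_EDGES.items():
            put("DPD_LB", m, 0.5 * w)
    else:
        for m, w in arch["dpd_onc"].items():
            put("DPD_onc", m, w)
        for m, w in _DPD_LB_EDGES.items():
            put("DPD_LB", m, w)

    return GroundTruthNetwork(driver_class=driver_class, r=r,
                              feedbacks=list(arch["feedbacks"]))


# --------------------------------------------------------------------------
# Dataset specification
# --------------------------------------------------------------------------


@dataclass
class DatasetSpec:
    """Layout and noise model of a synthetic cohort."""

    n_lines_per_class: int = 4        # luminal-cancer, basal-cancer, normal
    analyte_panel: dict = field(default_factory=lambda: dict(DEFAULT_PANEL))
    time_points_min: tuple = (0, 7, 9, 13, 17, 40, 60)
    inhibitors: dict = field(default_factory=lambda: dict(DEFAULT_INHIBITORS))
    n_cells_per_sample: int = 200
    sigma: float = 0.3                # lognormal single-cell spread
    batch_scale_range: tuple = (0.8, 1.25)
    lines_per_batch: int = 2
    control_line: str = "HCC70"
    egf_dose: float = 1.0
    line_jitter: float = 0.06         # per-line multiplicative edge jitter
    class_effect_scale: float = 0.3   # bystander class-mean spread (wide-margin
                                      # cohorts for robustness studies use more)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines_per_class < 1:
            raise ValueError("need at least one line per class")
        for name, (target, dose) in self.inhibitors.items():
            if dose < 0:
                raise ValueError(f"negative dose for inhibitor {name!r}")
            if target not in MODULES and not target.startswith("DPD"):
                raise ValueError(f"inhibitor {name!r} targets unknown module {target!r}")
        covered = {m for m in self.analyte_panel.values() if m is not None}
        if not set(MODULES) <= covered:
            raise ValueError("every core module needs at least one analyte readout")

    @property
    def conditions(self) -> list:
        return ["serum", "EGF"] + [f"EGF+{i}" for i in self.inhibitors]


@dataclass
class TruthBundle:
    """Generative truth exported with a synthetic dataset."""

    networks: dict                    # line -> GroundTruthNetwork
    labels: pd.DataFrame              # index = line; cancer, subtype
    dpd: pd.DataFrame                 # line, condition, time_min, DPD_onc, DPD_LB
    means: pd.DataFrame               # line, condition, time_min, analyte, mean
    activities: pd.DataFrame          # line, condition, time_min, module, activity
    spec: DatasetSpec
    seed: int


# DPD force parameters shared by generator twins (defaults of the twin module)
_DPD_PARAMS = {n: DPDDynamicsParams() for n in DPD_NODES}

# conversion of DPD in-edge coefficients to force coefficients
_S_REF = 1.4
_X_REF = 0.55


def _line_twin(network: GroundTruthNetwork, cancer: bool, subtype: str) -> TwinModel:
    basal = {"EGFR": 1.0, "PI3K_AKT": 0.1, "MEK_ERK": 0.5, "PKC": 0.06,
             "mTOR_S6K": 0.03, "STAT3": 0.3 if subtype == "luminal" else 0.15}
    s_init = {"DPD_onc": 0.2 if cancer else -0.2,
              "DPD_LB": 0.2 if subtype == "basal" else -0.2}
    return build_twin(network.r, significant=network.r.ne(0) & _offdiag(),
                      dpd_params=_DPD_PARAMS, s_ref=_S_REF, x_ref=_X_REF,
                      s_init=s_init, basal=basal)


def archetype_twin(network: GroundTruthNetwork, cancer: bool = True,
                   subtype: str = "basal") -> TwinModel:
    """The digital twin a generated line of this archetype evolves under.

    Exposes the generator's own dynamical model (module rates, basal
    drives, DPD force parameters) so that landscape and dose-response
    analyses can run on the ground-truth dynamics.
    """
    return _line_twin(network, cancer, subtype)


def _offdiag() -> pd.DataFrame:
    return pd.DataFrame(~np.eye(len(NODES), dtype=bool), index=NODES, columns=NODES)


def _line_table(spec: DatasetSpec):
    """Cohort layout: line names, labels, archetype assignment, batches."""
    lines, labels = [], []
    for i in range(spec.n_lines_per_class):
        lines.append(f"LUM{i + 1:02d}"); labels.append((1, "luminal"))
    for i in range(spec.n_lines_per_class):
        lines.append(f"BAS{i + 1:02d}"); labels.append((1, "basal"))
    for i in range(spec.n_lines_per_class):
        lines.append(f"NOR{i + 1:02d}"); labels.append((0, "NA"))
    label_df = pd.DataFrame(labels, index=pd.Index(lines, name="cell_line"),
                            columns=["cancer", "subtype"])
    batches = {}
    for k in range(0, len(lines), spec.lines_per_batch):
        batch = f"B{k // spec.lines_per_batch + 1:02d}"
        for ln in lines[k:k + spec.lines_per_batch]:
            batches[ln] = batch
    return lines, label_df, batches


def simulate_dataset(network: GroundTruthNetwork, spec: DatasetSpec,
                     conditions=None):
    """Simulate a synthetic single-cell dataset plus its generative truth.

    ``network`` is the cohort's cancer archetype; each cancer line receives
    a per-line jittered copy of it, each normal line a ``normal-weak``
    network.  Returns ``(cells, truth)`` where ``cells`` is a tidy
    DataFrame with one row per cell x analyte and ``truth`` is a
    :class:`TruthBundle`.

    ``conditions`` restricts the simulated conditions (e.g. ``["serum"]``
    for classification-only cohorts); default is the full design.
    """
    if network.driver_class == "normal-weak":
        raise ValueError("the cohort archetype must be a cancer driver class")
    rng = np.random.default_rng(spec.seed)
    wanted = list(spec.conditions if conditions is None else conditions)
    unknown = set(wanted) - set(spec.conditions)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")

    lines, label_df, batches = _line_table(spec)
    panel = spec.analyte_panel
    analytes = list(panel)

    # deterministic panel parameters
    prng = np.random.default_rng(spec.seed + 101)
    ces = spec.class_effect_scale
    base = {a: float(np.exp(prng.normal(np.log(50.0), 0.6))) for a in analytes}
    c_onc = {a: float(np.clip(prng.normal(0.0, ces), -0.6, None)) for a in analytes}
    c_lb = {a: float(np.clip(prng.normal(0.0, ces), -0.6, None)) for a in analytes}

    networks, mean_rows, act_rows, dpd_rows = {}, [], [], []
    for ln in lines:
        cancer = bool(label_df.loc[ln, "cancer"])
        subtype = label_df.loc[ln, "subtype"]
        line_seed = int(rng.integers(0, 2**31 - 1))
        if cancer:
            net = _jitter_network(network, spec.line_jitter, line_seed)
        else:
            net = make_ground_truth("normal-weak", seed=line_seed)
        networks[ln] = net
        model = _line_twin(net, cancer, subtype)
        lrng = np.random.default_rng(line_seed + 7)
        line_factor = {a: float(np.exp(lrng.normal(0.0, 0.10))) for a in analytes}

        try:
            y_starved = equilibrate(model, TreatmentSpec(egf=0.0), tol=1e-8)
        except Exception as exc:  # re-raise with the offending line named
            raise RuntimeError(
                f"equilibration failed for line {ln!r} "
                f"(driver={net.driver_class}): {exc}"
            ) from exc

        for cond in wanted:
            if cond == "serum":
                t_grid = np.array([0.0])
                states = {0.0: y_starved}
                trt = TreatmentSpec(egf=0.0)
            else:
                doses = {}
                if cond != "EGF":
                    inh = cond.split("+", 1)[1]
                    target, dose = spec.inhibitors[inh]
                    doses[target] = dose
                trt = TreatmentSpec(egf=spec.egf_dose, doses=doses)
                t_grid = np.asarray(spec.time_points_min, dtype=float)
                res = simulate(model, trt, t_grid, y0=y_starved)
                states = {float(t): res.states.loc[t].to_numpy()
                          for t in res.states.index}
            for t, y in states.items():
                acts = model.activities(y, trt, effective=True)
                for m, v in acts.items():
                    act_rows.append((ln, cond, t, m, v))
                dpd_rows.append((ln, cond, t,
                                 model.dpd_state(y, "DPD_onc"),
                                 model.dpd_state(y, "DPD_LB")))
                for a in analytes:
                    mod = panel[a]
                    if mod is None:
                        mu = base[a] * max(
                            0.15, 1.0 + c_onc[a] * cancer
                            + c_lb[a] * (subtype == "basal"))
                    else:
                        mu = base[a] * (0.15 + acts[mod])
                    mean_rows.append((ln, cond, t, a, mu * line_factor[a]))

    means = pd.DataFrame(mean_rows, columns=["cell_line", "condition",
                                             "time_min", "analyte", "mean"])
    acts_df = pd.DataFrame(act_rows, columns=["cell_line", "condition",
                                              "time_min", "module", "activity"])
    dpd_df = pd.DataFrame(dpd_rows, columns=["cell_line", "condition",
                                             "time_min", "DPD_onc", "DPD_LB"])

    cells = _sample_cells(means, batches, spec, analytes)
    truth = TruthBundle(networks=networks, labels=label_df, dpd=dpd_df,
                        means=means, activities=acts_df, spec=spec,
                        seed=spec.seed)
    return cells, truth


def _jitter_network(network: GroundTruthNetwork, jitter: float,
                    seed: int) -> GroundTruthNetwork:
    rng = np.random.default_rng(seed)
    r = network.r.copy()
    mask = (r != 0) & ~np.eye(len(r), dtype=bool)
    factors = rng.uniform(1 - jitter, 1 + jitter, size=r.shape)
    r = r.where(~mask, r * factors)
    # jitter must not hand the primary-driver role to another module
    driver = _DRIVER_MODULE[network.driver_class]
    onc = r.loc["DPD_onc", MODULES].abs()
    if onc.idxmax() != driver:
        top_other = onc.drop(driver).max()
        r.loc["DPD_onc", driver] = np.sign(r.loc["DPD_onc", driver] or 1.0) \
            * 1.02 * top_other
    return GroundTruthNetwork(driver_class=network.driver_class, r=r,
                              feedbacks=list(network.feedbacks))


def _sample_cells(means: pd.DataFrame, batches: dict, spec: DatasetSpec,
                  analytes: list) -> pd.DataFrame:
    """Draw per-cell intensities: lognormal cell noise x batch scale."""
    rng = np.random.default_rng(spec.seed + 2029)
    batch_names = sorted(set(batches.values()))
    lo, hi = spec.batch_scale_range
    bf = {(b, a): rng.uniform(lo, hi) for b in batch_names for a in analytes}

    # control-line reference samples: unstimulated baseline, one per batch,
    # identical generative means in every batch (the batch factor is the
    # only batch-dependent term, which normalization must cancel)
    crng = np.random.default_rng(spec.seed + 911)
    control_mean = {a: float(np.exp(crng.normal(np.log(50.0), 0.6)))
                    for a in analytes}

    n = spec.n_cells_per_sample
    sig = spec.sigma
    frames = []

    def draw(mu):
        if sig == 0:
            return np.full(n, mu)
        return mu * np.exp(rng.normal(0.0, sig, size=n) - 0.5 * sig * sig)

    for (ln, cond, t), grp in means.groupby(["cell_line", "condition", "time_min"],
                                            sort=False):
        batch = batches[ln]
        for a, mu in zip(grp["analyte"], grp["mean"]):
            vals = draw(mu * bf[(batch, a)])
            frames.append(pd.DataFrame({
                "cell_line": ln, "batch": batch, "condition": cond,
                "time_min": t, "cell_id": np.arange(n), "analyte": a,
                "intensity": vals,
            }))
    for b in batch_names:
        for a in analytes:
            vals = draw(control_mean[a] * bf[(b, a)])
            frames.append(pd.DataFrame({
                "cell_line": spec.control_line, "batch": b,
                "condition": "starved", "time_min": 0.0,
                "cell_id": np.arange(n), "analyte": a, "intensity": vals,
            }))
    cells = pd.concat(frames, ignore_index=True)
    if (cells["intensity"] <= 0).any():
        warnings.warn("clipping non-positive intensities to a small floor")
        cells["intensity"] = cells["intensity"].clip(lower=1e-9)
    return cells


# --------------------------------------------------------------------------
# Truth export
# --------------------------------------------------------------------------


def export_truth(truth: TruthBundle, path) -> None:
    """Write the generative truth to ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for ln, net in truth.networks.items():
        for tgt in NODES:
            for src in NODES:
                if src != tgt and net.r.loc[tgt, src] != 0:
                    rows.append((ln, net.driver_class, src, tgt,
                                 float(net.r.loc[tgt, src])))
    pd.DataFrame(rows, columns=["cell_line", "driver_class", "source",
                                "target", "r"]).to_csv(
        path / "edges.csv", index=False, float_format="%.17g")
    truth.dpd.to_csv(path / "dpd_truth.csv", index=False, float_format="%.17g")
    truth.labels.to_csv(path / "labels.csv")
    truth.means.to_csv(path / "means.csv", index=False, float_format="%.17g")
    meta = {
        "seed": truth.seed,
        "nodes": NODES,
        "panel": truth.spec.analyte_panel,
        "inhibitors": {k: list(v) for k, v in truth.spec.inhibitors.items()},
        "time_points_min": list(truth.spec.time_points_min),
        "sigma": truth.spec.sigma,
        "n_cells_per_sample": truth.spec.n_cells_per_sample,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_truth(path) -> dict:
    """Read back an exported truth directory."""
    path = Path(path)
    rt = {"float_precision": "round_trip"}
    return {
        "edges": pd.read_csv(path / "edges.csv", **rt),
        "dpd": pd.read_csv(path / "dpd_truth.csv", **rt),
        "labels": pd.read_csv(path / "labels.csv", index_col=0),
        "means": pd.read_csv(path / "means.csv", **rt),
        "meta": json.loads((path / "meta.json").read_text()),
    }
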