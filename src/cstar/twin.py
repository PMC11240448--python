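"""Mechanistic digital-twin ODE models of core signaling networks.

A twin couples three layers:

1. *Module activation dynamics.*  Each signaling module (a pathway lumped
   into one node, e.g. ``PI3K_AKT``) carries an active fraction
   ``x_j in [0, 1]`` obeying a activation/deactivation balance.  Crosstalk
   between modules enters through saturating *hyperbolic multipliers* on the
   activation rate, one per significant inferred connection, with the sign
   of the multiplier matching the sign of the connection coefficient.
2. *A mechanistic EGFR -> ERK cascade.*  When the twin contains both an
   ``EGFR`` and a ``MEK_ERK`` module linked by a significant edge, the
   single edge is replaced by an explicit receptor/RAS/RAF/MEK/ERK chain
   with ERK-mediated negative feedback onto SOS and RAF.
3. *Phenotype (DPD) dynamics.*  Each DPD node carries a scalar state ``S``
   driven by a piecewise-linear bistable restoring force plus a signaling
   force ``sigma(t) = sum_j beta_j x_j(t)`` contributed by the modules with
   significant connections into the DPD node.

Kinase inhibitors act divisively: a dose ``d`` (in Kd units) scales the
effective output of its target module by ``1 / (1 + d)`` everywhere the
module's activity is consumed (downstream edges, the signaling force, and
readouts).  For an mTOR inhibitor this scaling of the mTOR term of sigma is
exactly the direct brake on the phenotype drive that the dual
(mTOR + DPD) perturbation encodes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution

__all__ = [
    "DPDDynamicsParams",
    "DPDNode",
    "TreatmentSpec",
    "TwinModel",
    "TwinConvergenceError",
    "FitResult",
    "restoring_force",
    "signaling_betas",
    "signaling_force",
    "build_twin",
    "equilibrate",
    "simulate",
    "fit_twin",
]


class TwinConvergenceError(RuntimeError):
    """Raised when equilibration fails to reach a steady state."""


# --------------------------------------------------------------------------
# DPD force terms
# --------------------------------------------------------------------------


@dataclass
class DPDDynamicsParams:
    """Parameters of the bistable phenotype dynamics.

    ``s0 < 0 < s1`` are the two stable steady-state DPD positions (normal
    and oncogenic, or luminal and basal); ``alpha0``/``alpha1`` are the
    restoring-force slopes (1/min) on the lower/upper side.  The force has
    exactly three zeros: stable at ``s0`` and ``s1``, unstable at the
    midpoint.
    """

    alpha0: float = 2.0
    alpha1: float = 2.0
    s0: float = -1.0
    s1: float = 1.0

    def __post_init__(self) -> None:
        if not self.s0 < self.s1:
            raise ValueError(f"require s0 < s1, got s0={self.s0}, s1={self.s1}")
        if self.alpha0 <= 0 or self.alpha1 <= 0:
            raise ValueError("restoring-force slopes alpha0, alpha1 must be > 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.s0 + self.s1)

    @property
    def breakpoints(self) -> tuple[float, float, float]:
        s0, s1 = self.s0, self.s1
        return ((3 * s0 + s1) / 4, (s0 + s1) / 2, (s0 + 3 * s1) / 4)


def restoring_force(s, params: DPDDynamicsParams):
    """Piecewise-linear bistable restoring force ``f(S)``.

    Four branches, continuous everywhere, with zeros at ``s0``, the
    midpoint and ``s1``.  Accepts scalars or arrays.
    """
    p = params
    b1, mid, b3 = p.breakpoints
    s = np.asarray(s, dtype=float)
    out = np.select(
        [s < b1, s < mid, s < b3],
        [
            -p.alpha0 * (s - p.s0),
            p.alpha0 * (s - mid),
            p.alpha1 * (s - mid),
        ],
        default=-p.alpha1 * (s - p.s1),
    )
    return float(out) if out.ndim == 0 else out


def signaling_betas(r_s: dict, s_stst: float, x_stst: dict) -> dict:
    """Convert DPD in-edge coefficients to force coefficients.

    ``beta_j = r_Sj * S_stst / x_j_stst`` where the steady states are the
    pre-perturbation references.  Raises on a zero reference activity.
    """
    betas = {}
    for j, r in r_s.items():
        xr = x_stst[j]
        if xr == 0:
            raise ValueError(f"zero steady-state reference activity for module {j!r}")
        betas[j] = r * s_stst / xr
    return betas


def signaling_force(beta: dict, x: dict):
    """Signaling force ``sigma = sum_j beta_j x_j`` (scalar or time series)."""
    sigma = 0.0
    for j, b in beta.items():
        sigma = sigma + b * np.asarray(x[j], dtype=float)
    return float(sigma) if np.ndim(sigma) == 0 else sigma


@dataclass
class DPDNode:
    """One phenotype coordinate of the twin (e.g. ``DPD_onc``)."""

    name: str
    params: DPDDynamicsParams = field(default_factory=DPDDynamicsParams)
    beta: dict = field(default_factory=dict)  # module -> force coefficient
    s_init: float = 0.2


@dataclass
class TreatmentSpec:
    """Stimulation / inhibition protocol applied at t = 0.

    ``egf`` is the growth-factor input (dimensionless, 1 = saturating
    reference); ``doses`` maps target module -> inhibitor dose in Kd units
    (dose 1 halves the module's effective output).
    """

    egf: float = 0.0
    doses: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.egf < 0:
            raise ValueError("EGF dose must be >= 0")
        for mod, d in self.doses.items():
            if d < 0:
                raise ValueError(f"negative inhibitor dose for {mod!r}")

    def dose(self, module: str) -> float:
        return float(self.doses.get(module, 0.0))


# --------------------------------------------------------------------------
# The twin model
# --------------------------------------------------------------------------

#: default rate constants (1/min unless noted)
DEFAULT_RATES = {
    "kon": 0.5,       # EGF-EGFR association (x EGF)
    "koff": 0.2,      # EGF-EGFR dissociation
    "kdim": 2.0,      # dimerization + autophosphorylation (x bound^2)
    "kdp": 0.3,       # receptor dephosphorylation
    "egfr_basal": 0.01,
    "ksos": 0.8, "kdsos": 0.25,
    "kras": 1.0, "kdras": 0.35,
    "kraf": 1.0, "kdraf": 0.35,
    "kmek": 1.0, "kdmek": 0.35,
    "kerk": 1.0, "kderk": 0.35,
    "erk_fb": 2.0,    # ERK negative-feedback strength on SOS and RAF
    "kact": 0.5,      # generic module activation
    "kdeact": 0.15,   # generic module deactivation
    "mult_amp": 3.0,  # hyperbolic multiplier amplitude per unit |r|
    "mult_k": 0.3,    # hyperbolic multiplier half-saturation
}

_CASCADE = ("SOS", "RAS", "RAF", "MEK", "ERK")


class TwinModel:
    """ODE model of module activities and DPD phenotype states.

    Parameters
    ----------
    modules : list of str
        Signaling module names.  ``EGFR`` and ``MEK_ERK`` are recognised
        specially (receptor submodel; mechanistic ERK cascade).
    edges : dict
        ``(source, target) -> connection coefficient`` for the significant
        module-to-module edges.  Edge signs set the multiplier direction,
        magnitudes scale the multiplier amplitude.
    dpd_nodes : list of DPDNode
    rates, basal : dict, optional
        Overrides of :data:`DEFAULT_RATES` and of per-module basal drives.
    """

    def __init__(self, modules, edges=None, dpd_nodes=None, rates=None, basal=None):
        self.modules = list(modules)
        self.edges = dict(edges or {})
        for (u, v) in self.edges:
            if u not in self.modules or v not in self.modules:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown module")
        self.dpd_nodes = list(dpd_nodes or [])
        self.rates = dict(DEFAULT_RATES)
        if rates:
            self.rates.update(rates)
        self.basal = {m: 0.2 for m in self.modules}
        if basal:
            self.basal.update(basal)
        self.mechanistic_erk = (
            "EGFR" in self.modules
            and "MEK_ERK" in self.modules
            and ("EGFR", "MEK_ERK") in self.edges
        )
        self._layout()

    # -- state bookkeeping --------------------------------------------------

    def _layout(self) -> None:
        names = []
        if "EGFR" in self.modules:
            names += ["EGF_bound", "EGFR_act"]
        if self.mechanistic_erk:
            names += list(_CASCADE)
        self._generic = [
            m for m in self.modules
            if m != "EGFR" and not (m == "MEK_ERK" and self.mechanistic_erk)
        ]
        names += [f"x_{m}" for m in self._generic]
        names += [f"S_{d.name}" for d in self.dpd_nodes]
        self.state_names = names
        self._index = {n: i for i, n in enumerate(names)}

    def copy(self) -> "TwinModel":
        return copy.deepcopy(self)

    def initial_state(self) -> np.ndarray:
        y = np.full(len(self.state_names), 0.02)
        for m in self._generic:
            y[self._index[f"x_{m}"]] = 0.1
        for d in self.dpd_nodes:
            y[self._index[f"S_{d.name}"]] = d.s_init
        return y

    # -- activities ---------------------------------------------------------

    def raw_activity(self, y: np.ndarray, module: str) -> float:
        """Active fraction of a module from a state vector."""
        if module == "EGFR":
            return y[self._index["EGFR_act"]]
        if module == "MEK_ERK" and self.mechanistic_erk:
            return y[self._index["ERK"]]
        return y[self._index[f"x_{module}"]]

    def effective_activity(self, y, module, treatment: TreatmentSpec) -> float:
        """Inhibitor-scaled module output, ``x / (1 + dose)``."""
        return self.raw_activity(y, module) / (1.0 + treatment.dose(module))

    def activities(self, y: np.ndarray, treatment: TreatmentSpec | None = None,
                   effective: bool = True) -> dict:
        trt = treatment or TreatmentSpec()
        if effective:
            return {m: self.effective_activity(y, m, trt) for m in self.modules}
        return {m: self.raw_activity(y, m) for m in self.modules}

    def dpd_state(self, y: np.ndarray, name: str) -> float:
        return y[self._index[f"S_{name}"]]

    # -- dynamics -----------------------------------------------------------

    def _multiplier(self, y_src: float, weight: float) -> float:
        r = self.rates
        h = r["mult_amp"] * abs(weight) * y_src / (r["mult_k"] + y_src)
        return 1.0 + h if weight > 0 else 1.0 / (1.0 + h)

    def _drive(self, target: str, y: np.ndarray, trt: TreatmentSpec,
               skip_egfr_erk: bool = False) -> float:
        d = self.basal.get(target, 0.2)
        for (u, v), w in self.edges.items():
            if v != target:
                continue
            if skip_egfr_erk and u == "EGFR" and v == "MEK_ERK":
                continue
            d *= self._multiplier(self.effective_activity(y, u, trt), w)
        return d

    def rhs(self, t: float, y: np.ndarray, treatment: TreatmentSpec) -> np.ndarray:
        r = self.rates
        idx = self._index
        dy = np.zeros_like(y)
        trt = treatment

        if "EGFR" in self.modules:
            b = y[idx["EGF_bound"]]
            p = y[idx["EGFR_act"]]
            degfr = self._drive("EGFR", y, trt)
            dy[idx["EGF_bound"]] = r["kon"] * trt.egf * (1 - b) - r["koff"] * b
            dy[idx["EGFR_act"]] = (
                (r["kdim"] * b * b + r["egfr_basal"]) * degfr * (1 - p)
                - r["kdp"] * p
            )

        if self.mechanistic_erk:
            y_p = self.effective_activity(y, "EGFR", trt)
            y_erk = self.effective_activity(y, "MEK_ERK", trt)
            sos, ras, raf, mek, erk = (y[idx[n]] for n in _CASCADE)
            fb = 1.0 + r["erk_fb"] * y_erk
            dmek_drive = self._drive("MEK_ERK", y, trt, skip_egfr_erk=True)
            dy[idx["SOS"]] = r["ksos"] * y_p * (1 - sos) - r["kdsos"] * fb * sos
            dy[idx["RAS"]] = r["kras"] * sos * (1 - ras) - r["kdras"] * ras
            dy[idx["RAF"]] = r["kraf"] * ras * (1 - raf) - r["kdraf"] * fb * raf
            dy[idx["MEK"]] = r["kmek"] * raf * dmek_drive * (1 - mek) - r["kdmek"] * mek
            dy[idx["ERK"]] = r["kerk"] * mek * (1 - erk) - r["kderk"] * erk

        for m in self._generic:
            x = y[idx[f"x_{m}"]]
            dy[idx[f"x_{m}"]] = (
                r["kact"] * self._drive(m, y, trt) * (1 - x) - r["kdeact"] * x
            )

        for d in self.dpd_nodes:
            s = y[idx[f"S_{d.name}"]]
            sigma = sum(
                b * self.effective_activity(y, j, trt) for j, b in d.beta.items()
            )
            # scalar piecewise restoring force (hot path)
            p = d.params
            b1, mid, b3 = p.breakpoints
            if s < b1:
                f = -p.alpha0 * (s - p.s0)
            elif s < mid:
                f = p.alpha0 * (s - mid)
            elif s < b3:
                f = p.alpha1 * (s - mid)
            else:
                f = -p.alpha1 * (s - p.s1)
            dy[idx[f"S_{d.name}"]] = f + sigma
        return dy


# --------------------------------------------------------------------------
# Protocols
# --------------------------------------------------------------------------


def equilibrate(model: TwinModel, treatment: TreatmentSpec | None = None,
                y0: np.ndarray | None = None, tol: float = 1e-9,
                max_time: float = 1e5, chunk: float = 4000.0,
                rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate to steady state (``max |dy/dt| < tol``).

    Default treatment is the serum-starved, ligand-free condition
    (EGF = 0); the returned state is the initial condition for
    stimulation runs.
    """
    trt = treatment or TreatmentSpec(egf=0.0)
    y = model.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
    t_done = 0.0
    while t_done < max_time:
        sol = solve_ivp(model.rhs, (0.0, chunk), y, args=(trt,),
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise TwinConvergenceError(f"solver failure during equilibration: {sol.message}")
        y = sol.y[:, -1]
        t_done += chunk
        resid = float(np.max(np.abs(model.rhs(0.0, y, trt))))
        if resid < tol:
            return y
    raise TwinConvergenceError(
        f"no steady state within t={max_time:g} min (residual {resid:.3g}, "
        f"egf={trt.egf}, doses={trt.doses})"
    )


@dataclass
class SimResult:
    """Trajectories of one stimulation run."""

    t: np.ndarray
    states: pd.DataFrame          # columns = state names
    activities: pd.DataFrame      # effective module activities
    dpd: pd.DataFrame             # DPD states S(t) per phenotype node
    treatment: TreatmentSpec


def simulate(model: TwinModel, treatment: TreatmentSpec, t_grid,
             y0: np.ndarray | None = None, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimResult:
    """Simulate a treatment from an equilibrated initial condition."""
    t_grid = np.asarray(t_grid, dtype=float)
    if y0 is None:
        y0 = equilibrate(model)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t1 == t0:
        ys = np.repeat(np.asarray(y0, float)[:, None], len(t_grid), axis=1)
    else:
        sol = solve_ivp(model.rhs, (t0, t1), y0, args=(treatment,),
                        method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"twin simulation failed: {sol.message}")
        ys = sol.y
    states = pd.DataFrame(ys.T, index=t_grid, columns=model.state_names)
    acts = pd.DataFrame(
        {m: [model.effective_activity(ys[:, k], m, treatment)
             for k in range(ys.shape[1])] for m in model.modules},
        index=t_grid,
    )
    dpd = pd.DataFrame(
        {d.name: states[f"S_{d.name}"].to_numpy() for d in model.dpd_nodes},
        index=t_grid,
    )
    return SimResult(t=t_grid, states=states, activities=acts, dpd=dpd,
                     treatment=treatment)


# --------------------------------------------------------------------------
# Construction from an inferred network
# --------------------------------------------------------------------------


def build_twin(local_response: pd.DataFrame, significant: pd.DataFrame | None = None,
               dpd_params: dict | None = None, s_ref: float = 1.0,
               x_ref: float = 0.5, dpd_prefix: str = "DPD",
               s_init: dict | None = None, rates: dict | None = None,
               basal: dict | None = None) -> TwinModel:
    """Build a twin from an inferred local response matrix.

    Only edges flagged significant carry non-neutral multipliers.  Rows and
    columns of ``local_response`` are nodes (row = target, column =
    source); nodes whose name starts with ``dpd_prefix`` become phenotype
    nodes, the rest become signaling modules.  DPD in-edges are converted
    to force coefficients ``beta_j = r_Sj * s_ref / x_ref``; with no
    significant in-edges the DPD node evolves under the restoring force
    alone.
    """
    r = local_response
    if significant is None:
        significant = r.ne(0) & ~np.eye(len(r), dtype=bool)
        significant = pd.DataFrame(significant, index=r.index, columns=r.columns)
    nodes = list(r.index)
    dpd_names = [n for n in nodes if n.startswith(dpd_prefix)]
    modules = [n for n in nodes if n not in dpd_names]

    edges = {}
    for tgt in modules:
        for src in modules:
            if src == tgt:
                continue
            if bool(significant.loc[tgt, src]) and r.loc[tgt, src] != 0:
                edges[(src, tgt)] = float(r.loc[tgt, src])

    dpd_nodes = []
    for name in dpd_names:
        params = (dpd_params or {}).get(name, DPDDynamicsParams())
        beta = {
            src: float(r.loc[name, src]) * s_ref / x_ref
            for src in modules
            if bool(significant.loc[name, src]) and r.loc[name, src] != 0
        }
        init = (s_init or {}).get(name, 0.2)
        dpd_nodes.append(DPDNode(name=name, params=params, beta=beta, s_init=init))

    return TwinModel(modules, edges=edges, dpd_nodes=dpd_nodes,
                     rates=rates, basal=basal)


# --------------------------------------------------------------------------
# Parameter estimation
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    params: dict
    objective: float
    runs: list
    seed: int


def _apply_params(model: TwinModel, params: dict) -> TwinModel:
    m = model.copy()
    dpd_by_name = {d.name: d for d in m.dpd_nodes}
    for key, val in params.items():
        parts = key.split(":")
        kind = parts[0]
        if kind == "beta":
            _, dpd, mod = parts
            dpd_by_name[dpd].beta[mod] = val
        elif kind in ("alpha0", "alpha1", "s0", "s1"):
            _, dpd = parts
            setattr(dpd_by_name[dpd].params, kind, val)
        elif kind == "basal":
            m.basal[parts[1]] = val
        elif kind == "rate":
            m.rates[parts[1]] = val
        elif kind == "edge":
            _, src, tgt = parts
            m.edges[(src, tgt)] = val
        else:
            raise ValueError(f"unknown fit parameter {key!r}")
    return m


def _predict_columns(model, treatment, t_grid, y0, columns,
                     rtol=1e-6, atol=1e-8):
    """Fast array-only prediction of named observables on a time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(model.rhs, (float(t_grid[0]), float(t_grid[-1])), y0,
                    args=(treatment,), method="LSODA", t_eval=t_grid,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(sol.message)
    idx = model._index
    out = np.empty((len(t_grid), len(columns)))
    for c, name in enumerate(columns):
        key = f"S_{name}"
        if key in idx:
            out[:, c] = sol.y[idx[key]]
        else:
            if name == "EGFR":
                row = idx["EGFR_act"]
            elif name == "MEK_ERK" and model.mechanistic_erk:
                row = idx["ERK"]
            else:
                row = idx[f"x_{name}"]
            out[:, c] = sol.y[row] / (1.0 + treatment.dose(name))
    return out


def _objective(theta, model, names, datasets, equil_kwargs):
    trial = _apply_params(model, dict(zip(names, theta)))
    ssr = 0.0
    try:
        y0 = equilibrate(trial, **equil_kwargs)
    except TwinConvergenceError:
        return 1e12
    for treatment, t_grid, observed in datasets:
        try:
            pred = _predict_columns(trial, treatment, t_grid, y0,
                                    list(observed.columns))
        except RuntimeError:
            return 1e12
        resid = (pred - observed.to_numpy()).ravel()
        ssr += float(resid @ resid)
    return ssr


def fit_twin(model: TwinModel, datasets, bounds: dict, seed: int = 0,
             n_runs: int = 5, maxiter: int = 60, popsize: int = 12,
             tol: float = 1e-10, equil_kwargs: dict | None = None) -> FitResult:
    """Fit twin parameters to time-course data by differential evolution.

    ``datasets`` is a list of ``(TreatmentSpec, t_grid, observed)`` triples
    where ``observed`` is a DataFrame on ``t_grid`` whose columns are
    module names (effective activities) and/or DPD node names.  ``bounds``
    maps parameter keys (``"beta:<dpd>:<module>"``, ``"alpha1:<dpd>"``,
    ``"basal:<module>"``, ``"rate:<name>"``, ``"edge:<src>:<tgt>"``) to
    ``(low, high)`` tuples; every fitted parameter must be bounded.

    Runs ``n_runs`` independent optimizations from randomly sampled initial
    populations (seeded, reproducible) and returns the smallest-objective
    parameter set.
    """
    if not bounds:
        raise ValueError("bounds must name at least one parameter")
    for k, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"parameter {k!r} requires finite bounds with low < high")
    names = list(bounds)
    bnds = [bounds[k] for k in names]
    eq = {"tol": 1e-8, "max_time": 8000.0, "chunk": 4000.0,
          "rtol": 1e-7, "atol": 1e-9}
    if equil_kwargs:
        eq.update(equil_kwargs)

    runs = []
    for i in range(n_runs):
        res = differential_evolution(
            _objective, bnds, args=(model, names, datasets, eq),
            seed=seed + 1000 * i, maxiter=maxiter, popsize=popsize,
            tol=tol, polish=True, init="sobol", updating="deferred",
        )
        runs.append({"params": dict(zip(names, res.x)),
                     "objective": float(res.fun)})
    best = min(runs, key=lambda r: r["objective"])
    return FitResult(params=best["params"], objective=best["objective"],
                     runs=runs, seed=seed)
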