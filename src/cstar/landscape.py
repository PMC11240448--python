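"""Potentials, Waddington landscapes, dose responses and drug synergy.

The phenotype coordinate ``S`` moves in a double-well potential ``U(S)``
(the exact piecewise integral of the bistable restoring force) tilted by
the signaling force: ``W(S, t) = U(S) - sigma(t) * S``.  Valleys of ``W``
are attractor cell states; drug treatments reshape the landscape by
suppressing sigma.  A state switch is a saddle-node bifurcation: the
oncogenic attractor disappears once the net force pushing out of the upper
well exceeds ``alpha1 (S1 - S0) / 4``.

Dose-response curves record the steady-state DPD after equilibration under
each dose; Loewe isoboles trace the DPD = 0 contour in a two-drug dose
plane and classify the interaction by the contour's position relative to
the additivity chord (concave toward the origin = synergistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .twin import (
    DPDDynamicsParams,
    TreatmentSpec,
    TwinModel,
    TwinConvergenceError,
    equilibrate,
    restoring_force,
    simulate,
)

__all__ = [
    "PotentialCurve",
    "LandscapeSurface",
    "IsoboleGrid",
    "potential",
    "waddington",
    "critical_force",
    "constant_force_switch_threshold",
    "dose_response",
    "isoboles",
    "switch_threshold",
    "SwitchResult",
]


# --------------------------------------------------------------------------
# Potential and landscape
# --------------------------------------------------------------------------


@dataclass
class PotentialCurve:
    params: DPDDynamicsParams
    s_grid: np.ndarray
    u: np.ndarray
    barrier_height: float

    def __call__(self, s):
        return _potential(np.asarray(s, dtype=float), self.params)


def _potential(s, p: DPDDynamicsParams):
    """Exact piecewise integral of -f with gauge U(s0) = 0."""
    b1, mid, b3 = p.breakpoints
    d = p.s1 - p.s0
    u_b1 = p.alpha0 * d * d / 32.0
    u_mid = p.alpha0 * d * d / 16.0
    u_b3 = u_mid - p.alpha1 * d * d / 32.0
    s = np.asarray(s, dtype=float)
    out = np.select(
        [s < b1, s < mid, s < b3],
        [
            0.5 * p.alpha0 * (s - p.s0) ** 2,
            u_mid - 0.5 * p.alpha0 * (s - mid) ** 2,
            u_mid - 0.5 * p.alpha1 * (s - mid) ** 2,
        ],
        default=u_b3 + 0.5 * p.alpha1 * ((s - p.s1) ** 2 - (b3 - p.s1) ** 2),
    )
    return float(out) if out.ndim == 0 else out


def potential(params: DPDDynamicsParams, margin: float = 0.5,
              n: int = 401) -> PotentialCurve:
    """Double-well potential ``U`` with ``U' = -f`` and ``U(S0) = 0``.

    The grid spans ``[S0 - margin*(S1-S0), S1 + margin*(S1-S0)]``.  The
    barrier height is ``U(midpoint) - U(S0) = alpha0 (S1-S0)^2 / 16``.
    """
    d = params.s1 - params.s0
    s = np.linspace(params.s0 - margin * d, params.s1 + margin * d, n)
    u = _potential(s, params)
    return PotentialCurve(params=params, s_grid=s, u=u,
                          barrier_height=params.alpha0 * d * d / 16.0)


@dataclass
class LandscapeSurface:
    s_grid: np.ndarray
    t_grid: np.ndarray
    w: np.ndarray                    # shape (len(t), len(s))
    trajectory: np.ndarray | None    # S(t) overlay


def waddington(pot: PotentialCurve, sigma, t_grid=None,
               trajectory=None) -> LandscapeSurface:
    """Evolving landscape ``W(S, t) = U(S) - sigma(t) * S``."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    t_grid = (np.arange(len(sigma), dtype=float)
              if t_grid is None else np.asarray(t_grid, dtype=float))
    if len(t_grid) != len(sigma):
        raise ValueError("sigma and t_grid lengths differ")
    p = pot.params
    if trajectory is not None:
        traj = np.asarray(trajectory, dtype=float)
        if traj.min() < pot.s_grid.min() or traj.max() > pot.s_grid.max():
            raise ValueError("landscape grid does not cover the trajectory")
    w = pot.u[None, :] - sigma[:, None] * pot.s_grid[None, :]
    return LandscapeSurface(s_grid=pot.s_grid, t_grid=t_grid, w=w,
                            trajectory=None if trajectory is None
                            else np.asarray(trajectory, dtype=float))


def critical_force(params: DPDDynamicsParams, direction: str = "down") -> float:
    """Constant-force magnitude at which one attractor disappears.

    ``"down"``: force pushing from S1 toward S0 removes the upper well at
    ``alpha1 (S1 - S0) / 4``; ``"up"``: the lower well vanishes at
    ``alpha0 (S1 - S0) / 4``.
    """
    d = params.s1 - params.s0
    if direction == "down":
        return params.alpha1 * d / 4.0
    if direction == "up":
        return params.alpha0 * d / 4.0
    raise ValueError("direction must be 'up' or 'down'")


def constant_force_switch_threshold(params: DPDDynamicsParams,
                                    direction: str = "down",
                                    bracket_factor: float = 2.0,
                                    tol: float = 1e-4,
                                    t_max: float = 2000.0) -> float:
    """Numerically locate the saddle-node force by bisection.

    Integrates the pure phenotype dynamics ``dS/dt = f(S) - sigma`` (for
    the downward direction) starting at the attractor being destroyed and
    bisects the constant force magnitude at which the trajectory escapes
    to the other basin.
    """
    start = params.s1 if direction == "down" else params.s0
    sign = -1.0 if direction == "down" else 1.0
    mid = params.midpoint

    def switched(force_mag: float) -> bool:
        def rhs(t, y):
            return [restoring_force(y[0], params) + sign * force_mag]
        sol = solve_ivp(rhs, (0.0, t_max), [start], method="LSODA",
                        rtol=1e-9, atol=1e-11)
        s_end = sol.y[0, -1]
        return s_end < mid if direction == "down" else s_end > mid

    hi = critical_force(params, direction) * bracket_factor
    lo = 0.0
    if not switched(hi):
        raise RuntimeError("bracket failure: no switch at the upper bound")
    while hi - lo > tol:
        m = 0.5 * (lo + hi)
        if switched(m):
            hi = m
        else:
            lo = m
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Dose responses and synergy
# --------------------------------------------------------------------------


def _steady_dpd(model: TwinModel, treatment: TreatmentSpec, y0,
                dpd_node: str = "DPD_onc", t_max: float = 1e4,
                tol: float = 1e-8):
    """Steady-state DPD under a treatment, from a given initial state."""
    try:
        y = equilibrate(model, treatment, y0=y0, tol=tol, max_time=t_max,
                        chunk=min(2000.0, t_max))
        return float(model.dpd_state(y, dpd_node)), True
    except TwinConvergenceError:
        # report the end state, flagged unconverged
        res = simulate(model, treatment, np.linspace(0, t_max, 5), y0=y0)
        return float(res.dpd[dpd_node].iloc[-1]), False


def dose_response(model: TwinModel, inhibitors, doses,
                  combo_ratio=None, egf: float = 1.0,
                  dpd_node: str = "DPD_onc", t_max: float = 1e4,
                  y0=None) -> pd.DataFrame:
    """Steady-state DPD versus dose for single drugs or a fixed-ratio combo.

    ``inhibitors`` is a target module name or a list of them; for a
    combination ``combo_ratio`` gives each drug's fraction of the total
    dose (default equal split).  The model is first equilibrated untreated
    (EGF present) — the baseline cell state — and each dose is then
    applied at t = 0.  Non-convergent doses are flagged, not fatal.
    """
    if isinstance(inhibitors, str):
        inhibitors = [inhibitors]
    if combo_ratio is None:
        combo_ratio = [1.0 / len(inhibitors)] * len(inhibitors)
    if len(combo_ratio) != len(inhibitors):
        raise ValueError("combo_ratio length must match the drug list")
    if not np.isclose(sum(combo_ratio), 1.0):
        raise ValueError("combo_ratio must sum to 1")
    baseline = TreatmentSpec(egf=egf)
    if y0 is None:
        y0 = equilibrate(model, baseline, tol=1e-8)
    rows = []
    for dose in np.asarray(doses, dtype=float):
        trt = TreatmentSpec(egf=egf,
                            doses=_dose_map(inhibitors, combo_ratio, dose))
        s, ok = _steady_dpd(model, trt, y0, dpd_node, t_max=t_max)
        rows.append({"dose": dose, dpd_node: s, "converged": ok})
    return pd.DataFrame(rows)


def _dose_map(inhibitors, fractions, total_dose) -> dict:
    """Accumulate doses additively (two drugs on one target add up)."""
    doses: dict = {}
    for m, f in zip(inhibitors, fractions):
        doses[m] = doses.get(m, 0.0) + total_dose * f
    return doses


@dataclass
class SwitchResult:
    switched: bool
    critical_dose: float | None
    post_state_dpd: float | None


def switch_threshold(model: TwinModel, inhibitors, combo_ratio=None,
                     max_dose: float = 100.0, egf: float = 1.0,
                     dpd_node: str = "DPD_onc", tol: float = 0.01,
                     y0=None) -> SwitchResult:
    """Bisect the total dose at which the oncogenic attractor disappears.

    Returns the critical dose and the post-switch steady-state DPD, or a
    resistant ("no switch") result if the sign never flips up to
    ``max_dose``.
    """
    if isinstance(inhibitors, str):
        inhibitors = [inhibitors]
    if combo_ratio is None:
        combo_ratio = [1.0 / len(inhibitors)] * len(inhibitors)
    baseline = TreatmentSpec(egf=egf)
    if y0 is None:
        y0 = equilibrate(model, baseline, tol=1e-8)
    base_dpd = float(model.dpd_state(y0, dpd_node))
    if base_dpd <= 0:
        raise ValueError("baseline state is not oncogenic (DPD <= 0)")

    def final_dpd(total_dose):
        trt = TreatmentSpec(egf=egf,
                            doses=_dose_map(inhibitors, combo_ratio, total_dose))
        s, _ = _steady_dpd(model, trt, y0, dpd_node)
        return s

    if final_dpd(max_dose) > 0:
        return SwitchResult(switched=False, critical_dose=None,
                            post_state_dpd=None)
    lo, hi = 0.0, max_dose
    while hi - lo > tol * max(1.0, hi):
        m = 0.5 * (lo + hi)
        if final_dpd(m) < 0:
            hi = m
        else:
            lo = m
    return SwitchResult(switched=True, critical_dose=0.5 * (lo + hi),
                        post_state_dpd=final_dpd(hi))


@dataclass
class IsoboleGrid:
    drug_pair: tuple
    contour: pd.DataFrame          # dose1, dose2 points on the DPD = 0 contour
    intercepts: tuple              # (I1, I2) single-drug switch doses
    loewe_index: float             # mean d1/I1 + d2/I2 over interior points
    synergy_class: str             # synergistic | additive | antagonistic


def isoboles(model: TwinModel, drug_pair, max_dose: float = 100.0,
             n: int = 9, egf: float = 1.0, dpd_node: str = "DPD_onc",
             additive_tol: float = 0.02, tol: float = 0.01) -> IsoboleGrid:
    """Loewe isobole of the DPD = 0 switch contour for a drug pair.

    Finds each drug's single-agent switch dose (the axis intercepts), then
    bisects the second drug's dose along a grid of first-drug doses.  The
    interaction is classified by the mean Loewe sum ``d1/I1 + d2/I2`` of
    interior contour points: below ``1 - additive_tol`` synergistic
    (contour concave toward the origin), above ``1 + additive_tol``
    antagonistic, else additive.
    """
    m1, m2 = drug_pair
    baseline = TreatmentSpec(egf=egf)
    y0 = equilibrate(model, baseline, tol=1e-8)

    def steady(d1, d2):
        doses = {m1: d1}
        doses[m2] = doses.get(m2, 0.0) + d2
        trt = TreatmentSpec(egf=egf, doses=doses)
        s, _ = _steady_dpd(model, trt, y0, dpd_node)
        return s

    def bisect(fun, hi):
        if fun(hi) > 0:
            return None
        lo_, hi_ = 0.0, hi
        while hi_ - lo_ > tol * max(1.0, hi_):
            mid = 0.5 * (lo_ + hi_)
            if fun(mid) < 0:
                hi_ = mid
            else:
                lo_ = mid
        return 0.5 * (lo_ + hi_)

    i1 = bisect(lambda d: steady(d, 0.0), max_dose)
    i2 = bisect(lambda d: steady(0.0, d), max_dose)
    if i1 is None or i2 is None:
        warnings.warn("no single-agent switch in the dose range; "
                      "isobole contour absent")
        return IsoboleGrid(drug_pair=(m1, m2), contour=pd.DataFrame(),
                           intercepts=(i1, i2), loewe_index=float("nan"),
                           synergy_class="no switch in range")

    points = [(0.0, i2)]
    for d1 in np.linspace(0.0, i1, n)[1:-1]:
        d2 = bisect(lambda d: steady(d1, d), max_dose)
        if d2 is not None:
            points.append((float(d1), float(d2)))
    points.append((i1, 0.0))
    contour = pd.DataFrame(points, columns=["dose1", "dose2"])

    interior = contour.iloc[1:-1]
    if interior.empty:
        loewe = 1.0
    else:
        loewe = float((interior["dose1"] / i1 + interior["dose2"] / i2).mean())
    if loewe < 1.0 - additive_tol:
        cls = "synergistic"
    elif loewe > 1.0 + additive_tol:
        cls = "antagonistic"
    else:
        cls = "additive"
    return IsoboleGrid(drug_pair=(m1, m2), contour=contour,
                       intercepts=(i1, i2), loewe_index=loewe,
                       synergy_class=cls)
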