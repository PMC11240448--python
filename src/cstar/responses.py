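"""Global response matrices and perturbation bookkeeping for network inference.

A perturbation experiment compares matched samples with and without a drug
at the same time point after EGF stimulation.  Module responses use the
bounded fractional change

    R = 2 (x1 - x0) / (x1 + x0)        (module outputs, in (-2, 2))

and phenotype (DPD) responses use the relative change of the signed score

    R = (DPD1 - DPD0) / DPD0           (undefined at DPD0 = 0).

Experiments are grouped into early (7, 9, 13, 17 min) and late
(40, 60 min) time points and concatenated column-wise; consensus matrices
further concatenate across cell lines.  Alongside R, the assembly produces
the perturbation matrix (which nodes each experiment hits directly; mTOR
inhibitors perturb both the mTOR module and the DPD nodes) and the prior
topology with forbidden DPD -> signaling connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .syndata import DPD_NODES, MODULES, MODULE_OUTPUTS

__all__ = [
    "global_response",
    "global_response_dpd",
    "TIME_GROUPS",
    "default_prior",
    "default_perturbation_targets",
    "ResponseInputs",
    "assemble_inputs",
]

#: early/late time-point grouping (minutes after EGF)
TIME_GROUPS = {"early": (7.0, 9.0, 13.0, 17.0), "late": (40.0, 60.0)}

PRIOR_EDGE = 1
PRIOR_NONE = 0
PRIOR_FORBIDDEN = -1


def global_response(x0: float, x1: float) -> float:
    """Bounded fractional response ``2 (x1 - x0) / (x1 + x0)``.

    Antisymmetric under swapping the two values and confined to
    ``[-2, 2]``; undefined when both values are zero.
    """
    if x0 < 0 or x1 < 0:
        raise ValueError("module outputs must be non-negative")
    s = x0 + x1
    if s == 0:
        raise ValueError("undefined response: x0 + x1 = 0")
    return 2.0 * (x1 - x0) / s


def global_response_dpd(dpd0: float, dpd1: float) -> float:
    """Relative DPD response ``(dpd1 - dpd0) / dpd0``.

    The baseline must be off the separating plane (``dpd0 != 0``).
    """
    if dpd0 == 0:
        raise ValueError("undefined DPD response: baseline score is 0 "
                         "(sample on the separating plane)")
    return (dpd1 - dpd0) / dpd0


def default_prior(nodes=None) -> pd.DataFrame:
    """No-crosstalk pathway backbone prior with forbidden DPD out-edges.

    Entries: 1 expected edge, 0 no prior, -1 forbidden.  Rows are targets,
    columns sources; the diagonal is excluded (0).
    """
    nodes = list(nodes) if nodes is not None else MODULES + DPD_NODES
    prior = pd.DataFrame(PRIOR_NONE, index=nodes, columns=nodes, dtype=int)
    backbone = [("EGFR", "PI3K_AKT"), ("EGFR", "MEK_ERK"), ("EGFR", "STAT3"),
                ("EGFR", "PKC"), ("PI3K_AKT", "mTOR_S6K")]
    for src, tgt in backbone:
        if src in nodes and tgt in nodes:
            prior.loc[tgt, src] = PRIOR_EDGE
    for dpd in DPD_NODES:
        if dpd in nodes:
            prior.loc[:, dpd] = PRIOR_FORBIDDEN  # no outgoing DPD edges
            prior.loc[dpd, dpd] = PRIOR_NONE
    return prior


def default_perturbation_targets(inhibitors: dict) -> dict:
    """Map inhibitor -> directly perturbed nodes.

    mTOR inhibitors additionally perturb both DPD nodes (the phenotype
    readout retains mTOR-module analytes, so modular insulation requires
    marking the DPD modules as directly hit).
    """
    targets = {}
    for name, spec in inhibitors.items():
        module = spec[0] if isinstance(spec, (tuple, list)) else spec
        hit = [module]
        if module == "mTOR_S6K":
            hit += list(DPD_NODES)
        targets[name] = hit
    return targets


@dataclass
class ResponseInputs:
    """Assembled inputs for Bayesian modular response analysis."""

    R: pd.DataFrame              # nodes x experiments
    perturbation: pd.DataFrame   # experiments x nodes (0/1)
    prior: pd.DataFrame          # nodes x nodes ternary
    metadata: pd.DataFrame       # per-experiment inhibitor, time, cell line


def assemble_inputs(markers: pd.DataFrame, dpd_scores: pd.DataFrame,
                    inhibitor_targets: dict | None = None,
                    module_outputs: dict | None = None,
                    time_group: str = "late", cell_lines=None,
                    prior: pd.DataFrame | None = None,
                    inhibitors=None, dpd_floor: float = 0.05) -> ResponseInputs:
    """Build (R, perturbation matrix, prior) from a normalized marker table.

    Parameters
    ----------
    markers : normalized table with cell_line, condition, time_min,
        analyte, value; conditions ``"EGF"`` (no drug) and ``"EGF+<inh>"``.
    dpd_scores : per-sample reduced-panel DPD scores with columns
        cell_line, condition, time_min and one column per DPD node.
    time_group : "early", "late" or "all" — which time points to
        concatenate into experiment columns.
    cell_lines : restrict / order the lines; with more than one line the
        result is a consensus matrix (columns concatenated across lines).
    dpd_floor : experiments whose baseline |DPD| falls below this are
        dropped with a warning instead of producing exploding ratios.
    """
    module_outputs = dict(module_outputs or MODULE_OUTPUTS)
    nodes = list(module_outputs) + [c for c in dpd_scores.columns
                                    if c.startswith("DPD")]
    if time_group == "all":
        times = TIME_GROUPS["early"] + TIME_GROUPS["late"]
    else:
        try:
            times = TIME_GROUPS[time_group]
        except KeyError:
            raise ValueError(f"unknown time group {time_group!r}") from None

    conds = set(markers["condition"].unique())
    inhibitor_names = sorted(
        c.split("+", 1)[1] for c in conds if c.startswith("EGF+")
    ) if inhibitors is None else list(inhibitors)
    if inhibitor_targets is None:
        from .syndata import DEFAULT_INHIBITORS
        try:
            inhibitor_targets = default_perturbation_targets(
                {i: DEFAULT_INHIBITORS[i] for i in inhibitor_names})
        except KeyError as exc:
            raise ValueError(
                f"no default target known for inhibitor {exc}; pass "
                "inhibitor_targets explicitly"
            ) from None
    lines = (sorted(markers["cell_line"].unique())
             if cell_lines is None else list(cell_lines))

    mk = markers.set_index(["cell_line", "condition", "time_min", "analyte"])["value"]
    dp = dpd_scores.set_index(["cell_line", "condition", "time_min"])

    cols, pert_rows, meta = {}, [], []
    for line in lines:
        for inh in inhibitor_names:
            cond1 = f"EGF+{inh}"
            for t in times:
                key = f"{line}|{inh}|t{t:g}"
                col = []
                try:
                    for node in nodes:
                        if node.startswith("DPD"):
                            d0 = float(dp.loc[(line, "EGF", t), node])
                            d1 = float(dp.loc[(line, cond1, t), node])
                            if abs(d0) < dpd_floor:
                                warnings.warn(
                                    f"dropping experiment {key}: baseline "
                                    f"|{node}|={abs(d0):.3g} < {dpd_floor}"
                                )
                                raise _DropExperiment
                            col.append(global_response_dpd(d0, d1))
                        else:
                            a = module_outputs[node]
                            x0 = float(mk.loc[(line, "EGF", t, a)])
                            x1 = float(mk.loc[(line, cond1, t, a)])
                            col.append(global_response(x0, x1))
                except _DropExperiment:
                    continue
                except KeyError as exc:
                    raise ValueError(
                        f"missing matched sample for experiment {key}: {exc}"
                    ) from None
                cols[key] = col
                hit = inhibitor_targets[inh]
                pert_rows.append([1 if n in hit else 0 for n in nodes])
                meta.append({"experiment": key, "cell_line": line,
                             "inhibitor": inh, "time_min": t})

    if not cols:
        raise ValueError("no usable experiments (all dropped or missing)")
    R = pd.DataFrame(cols, index=nodes)
    pert = pd.DataFrame(pert_rows, index=list(cols), columns=nodes)
    prior = default_prior(nodes) if prior is None else prior
    return ResponseInputs(R=R, perturbation=pert, prior=prior,
                          metadata=pd.DataFrame(meta))


class _DropExperiment(Exception):
    pass
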