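"""Per-sample aggregation and in-batch control normalization.

Single-cell intensities are averaged per sample (one sample = one cell
line x condition x time point), then each per-analyte mean is divided by
the average signal of that analyte in the batch's shared control line.
This makes values dimensionless ratios, cancels per-batch scale factors
exactly, and maps the control line itself to 1.0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["aggregate", "batch_normalize", "feature_matrix"]

_SAMPLE_KEYS = ["cell_line", "batch", "condition", "time_min", "analyte"]


def aggregate(cells: pd.DataFrame, statistic: str = "mean",
              min_cells_warn: int = 10) -> pd.DataFrame:
    """Average single cells to one value per (line, condition, time, analyte).

    ``statistic`` is ``"mean"`` (default, matching ratio normalization of
    raw intensities) or ``"median"``.  Samples with fewer than
    ``min_cells_warn`` cells trigger a warning; empty samples are an error
    (they cannot occur in a well-formed table but guard against upstream
    filtering).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    required = set(_SAMPLE_KEYS + ["intensity"])
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    if cells.empty:
        raise ValueError("empty cell table")

    grouped = cells.groupby(_SAMPLE_KEYS, sort=False, observed=True)["intensity"]
    counts = grouped.size()
    small = counts[counts < min_cells_warn]
    if len(small):
        key = small.index[0]
        warnings.warn(
            f"{len(small)} sample(s) with fewer than {min_cells_warn} cells "
            f"(e.g. {key})"
        )
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    out = agg.rename("value").reset_index()
    return out


def batch_normalize(means: pd.DataFrame, control_line: str) -> pd.DataFrame:
    """Divide each per-analyte value by the in-batch control-line mean.

    The control line must be present in every batch; a zero control mean
    is an error.  Returns the table without the control line's own rows
    normalized to 1.0 (they are kept, flagged by ``cell_line``).
    """
    required = {"cell_line", "batch", "analyte", "value"}
    missing = required - set(means.columns)
    if missing:
        raise ValueError(f"mean table lacks columns: {sorted(missing)}")

    batches = means["batch"].unique()
    ctrl = means[means["cell_line"] == control_line]
    ctrl_batches = set(ctrl["batch"].unique())
    absent = [b for b in batches if b not in ctrl_batches]
    if absent:
        raise ValueError(
            f"control line {control_line!r} missing from batch(es): {absent}"
        )
    ref = (ctrl.groupby(["batch", "analyte"], observed=True)["value"]
           .mean().rename("control_mean"))
    if (ref == 0).any():
        bad = ref[ref == 0].index.tolist()[:3]
        raise ValueError(f"zero control mean for (batch, analyte): {bad}")

    out = means.merge(ref.reset_index(), on=["batch", "analyte"], how="left")
    out["value"] = out["value"] / out["control_mean"]
    return out.drop(columns="control_mean")


def feature_matrix(markers: pd.DataFrame, condition: str = "serum",
                   time_min: float | None = None,
                   exclude: tuple = ()) -> pd.DataFrame:
    """Pivot a normalized marker table to a (line x analyte) matrix."""
    sel = markers[markers["condition"] == condition]
    if time_min is not None:
        sel = sel[sel["time_min"] == time_min]
    sel = sel[~sel["cell_line"].isin(exclude)]
    mat = sel.pivot_table(index="cell_line", columns="analyte", values="value",
                          aggfunc="mean")
    if mat.isna().any().any():
        raise ValueError("incomplete marker table: missing (line, analyte) values")
    return mat
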