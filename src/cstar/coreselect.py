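"""Core-network selection from STV component rankings.

The absolute values of the STV components rank how much each analyte
contributes to the state transition; the highly ranked analytes delimit a
core network of signaling modules.  Before network inference the analytes
mapped to the core modules are removed from the panel and the
separator/DPD is refit on the remainder, so that the phenotype readout is
insulated from the modules whose causal influence on it is being inferred.
A small set of exceptions (by default pS6 and pSTAT3) stays in both the
phenotype panel and the core network, a concession to panels with few
analytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .separator import StateSeparator

__all__ = ["CoreSelection", "rank_stv", "select_core_modules",
           "recompute_dpd_excluding_core", "DEFAULT_EXCEPTIONS"]

DEFAULT_EXCEPTIONS = ("pS6", "pSTAT3")


@dataclass
class CoreSelection:
    ranking: pd.DataFrame              # analyte, component, rank
    module_map: dict                   # analyte -> module (or None)
    modules: list = field(default_factory=list)
    exceptions: tuple = DEFAULT_EXCEPTIONS

    def core_analytes(self) -> list:
        return [a for a, m in self.module_map.items() if m in self.modules]


def rank_stv(separator: StateSeparator) -> pd.DataFrame:
    """Rank analytes by |STV component|, descending; ties break by name."""
    comps = np.abs(separator.stv_)
    names = separator.analytes_ or [f"a{i}" for i in range(len(comps))]
    df = pd.DataFrame({"analyte": names, "component": separator.stv_,
                       "abs_component": comps})
    df = df.sort_values(["abs_component", "analyte"],
                        ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def select_core_modules(separator: StateSeparator, module_map: dict,
                        n_modules: int = 6,
                        exceptions: tuple = DEFAULT_EXCEPTIONS) -> CoreSelection:
    """Pick the top modules by their best-ranked analyte component.

    Modules are scored by the largest |STV component| among their mapped
    analytes; the top ``n_modules`` constitute the core network.
    """
    ranking = rank_stv(separator)
    scores = {}
    for _, row in ranking.iterrows():
        mod = module_map.get(row["analyte"])
        if mod is not None:
            scores.setdefault(mod, row["abs_component"])
    top = sorted(scores, key=lambda m: -scores[m])[:n_modules]
    return CoreSelection(ranking=ranking, module_map=dict(module_map),
                         modules=top, exceptions=tuple(exceptions))


def recompute_dpd_excluding_core(features: pd.DataFrame, labels,
                                 core_analytes, exceptions: tuple = DEFAULT_EXCEPTIONS,
                                 positive_class=None, C: float = 1e6):
    """Refit the separator after removing core-network analytes.

    All analytes mapped to the selected core modules are dropped together,
    except the stated exceptions which remain in the feature set.  Returns
    ``(separator, scores)`` where ``scores`` are training-set DPD values on
    the reduced panel.  If the classes are no longer perfectly separated a
    warning reports the off-diagonal confusion counts.
    """
    if not isinstance(features, pd.DataFrame):
        raise TypeError("features must be a DataFrame with analyte columns")
    unknown = set(core_analytes) - set(features.columns)
    if unknown:
        raise ValueError(f"core analytes not in the panel: {sorted(unknown)}")
    drop = [a for a in core_analytes if a not in exceptions]
    reduced = features.drop(columns=drop)
    if reduced.shape[1] == 0:
        raise ValueError("core removal left an empty panel")

    sep = StateSeparator(C=C, positive_class=positive_class).fit(reduced, labels)
    pred = sep.predict(reduced)
    y = np.asarray(labels)
    wrong = int((pred != y).sum())
    if wrong:
        warnings.warn(
            f"reduced-panel separator misclassifies {wrong}/{len(y)} training "
            "samples (off-diagonal confusion counts)"
        )
    scores = pd.Series(sep.dpd_score(reduced), index=reduced.index, name="dpd")
    return sep, scores
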