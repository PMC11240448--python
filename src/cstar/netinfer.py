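"""Bayesian modular response analysis (BMRA).

Modular response analysis relates the local response matrix ``r`` (direct,
causal connection coefficients between network modules, diagonal fixed at
-1) to measured global responses ``R`` through the steady-state constraint

    sum_j r_ij R_jk = 0   for every experiment k that does not directly
                          perturb module i.

Per target module this is a linear regression of the module's own global
responses on those of the candidate source modules.  The Bayesian layer
places spike-and-slab indicators on candidate in-edges (prior inclusion
0.5 for unknown edges, higher for prior-backbone edges, 0 for forbidden
edges), a Zellner g-prior on the coefficients, enumerates candidate edge
sets exhaustively, restricts model averaging to an Occam's window (models
whose posterior mass is at least a stated fraction of the best model's)
and reports model-averaged coefficients, credible intervals and edge
inclusion probabilities.  Prior edges are favored but removable; forbidden
edges are never included.

The inverse relation ``R_xI = -r^{-1} r_xI`` forward-predicts global
responses (including the phenotype rows) to fresh inhibitor perturbations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

from .responses import PRIOR_EDGE, PRIOR_FORBIDDEN, ResponseInputs

__all__ = [
    "BayesianMRA",
    "infer",
    "forward_predict",
    "DriverRanking",
    "rank_drivers",
    "cluster_driver_profiles",
]


class BayesianMRA(BaseEstimator):
    """Spike-and-slab BMRA with exhaustive edge-set enumeration.

    Parameters
    ----------
    g : float
        Zellner g-prior scale.  Large values give essentially
        likelihood-driven coefficient magnitudes while the Bayes-factor
        dimensionality penalty ``(1+g)^(-p/2)`` still enforces parsimony.
    occam : float
        Occam's window: models with posterior probability at least
        ``occam`` times the best model's are averaged.
    prior_inclusion, prior_edge_inclusion : float
        Prior edge-inclusion probabilities for unknown and prior-backbone
        edges.
    ci_level : float
        Credible-interval mass used for the significance call (an edge is
        significant iff its interval excludes 0).
    max_exhaustive : int
        Largest candidate in-degree enumerated exhaustively; beyond it the
        candidate set is trimmed to the strongest marginal correlates.

    Attributes (after :meth:`fit`)
    ------------------------------
    nodes_ : node order
    local_response_ : DataFrame, model-averaged r (diagonal -1)
    ci_low_, ci_high_ : DataFrames, credible-interval bounds
    inclusion_ : DataFrame, posterior edge-inclusion probabilities
    significant_ : DataFrame of booleans
    """

    def __init__(self, g: float = 1e7, occam: float = 0.2,
                 prior_inclusion: float = 0.5, prior_edge_inclusion: float = 0.9,
                 ci_level: float = 0.95, n_draws: int = 4000,
                 max_exhaustive: int = 12, random_state: int | None = 0):
        self.g = g
        self.occam = occam
        self.prior_inclusion = prior_inclusion
        self.prior_edge_inclusion = prior_edge_inclusion
        self.ci_level = ci_level
        self.n_draws = n_draws
        self.max_exhaustive = max_exhaustive
        self.random_state = random_state

    # ------------------------------------------------------------------

    def fit(self, R, perturbation=None, prior=None):
        """Infer the local response matrix.

        ``R`` may be a :class:`~cstar.responses.ResponseInputs` bundle or a
        (nodes x experiments) DataFrame accompanied by a
        (experiments x nodes) perturbation indicator DataFrame and an
        optional ternary prior matrix.
        """
        if isinstance(R, ResponseInputs):
            prior = R.prior
            perturbation = R.perturbation
            R = R.R
        if perturbation is None:
            raise ValueError("a perturbation matrix is required")
        nodes = list(R.index)
        if prior is None:
            prior = pd.DataFrame(0, index=nodes, columns=nodes, dtype=int)
        Rv = R.to_numpy(dtype=float)
        if not np.all(np.isfinite(Rv)):
            raise ValueError("global response matrix contains non-finite values")
        P = perturbation.reindex(columns=nodes).to_numpy(dtype=float)
        rng = np.random.default_rng(self.random_state)

        n_nodes = len(nodes)
        mean = np.zeros((n_nodes, n_nodes))
        lo = np.zeros((n_nodes, n_nodes))
        hi = np.zeros((n_nodes, n_nodes))
        incl = np.zeros((n_nodes, n_nodes))
        np.fill_diagonal(mean, -1.0)
        np.fill_diagonal(lo, -1.0)
        np.fill_diagonal(hi, -1.0)

        for i, node in enumerate(nodes):
            free = np.flatnonzero(P[:, i] == 0)
            if free.size < 1:
                raise ValueError(
                    f"node {node!r}: every experiment perturbs it directly; "
                    "no MRA constraints available"
                )
            cand = [j for j in range(n_nodes)
                    if j != i and prior.iloc[i, j] != PRIOR_FORBIDDEN]
            if not cand:
                continue
            has_prior = any(prior.iloc[i, j] == PRIOR_EDGE for j in cand)
            if free.size < len(cand) and not has_prior:
                raise ValueError(
                    f"node {node!r}: {free.size} constraint(s) for {len(cand)} "
                    "candidate in-edges and no prior to regularize; supply a "
                    "prior topology or reduce the node set"
                )
            y = Rv[i, free]
            X = Rv[np.ix_(cand, free)].T  # n_exp x n_cand
            pi = np.array([
                self.prior_edge_inclusion if prior.iloc[i, j] == PRIOR_EDGE
                else self.prior_inclusion for j in cand
            ])
            m, l, h, q = self._fit_node(y, X, pi, rng)
            for a, j in enumerate(cand):
                mean[i, j] = m[a]
                lo[i, j] = l[a]
                hi[i, j] = h[a]
                incl[i, j] = q[a]

        self.nodes_ = nodes
        as_df = lambda a: pd.DataFrame(a, index=nodes, columns=nodes)
        self.local_response_ = as_df(mean)
        self.ci_low_ = as_df(lo)
        self.ci_high_ = as_df(hi)
        self.inclusion_ = as_df(incl)
        sig = (self.ci_low_ > 0) | (self.ci_high_ < 0)
        np.fill_diagonal(sig.values, False)
        self.significant_ = sig
        return self

    # ------------------------------------------------------------------

    def _fit_node(self, y, X, pi, rng):
        n, p_all = X.shape
        g = self.g
        yty = float(y @ y)
        cand_idx = np.arange(p_all)
        if p_all > self.max_exhaustive:
            # keep prior edges and the strongest marginal correlates
            score = np.abs(X.T @ y) + 1e6 * (pi > self.prior_inclusion)
            keep = np.argsort(-score)[: self.max_exhaustive]
            warnings.warn(
                f"{p_all} candidate in-edges exceed max_exhaustive="
                f"{self.max_exhaustive}; trimming to the strongest candidates"
            )
            cand_idx = np.sort(keep)

        models = []
        log_pi = np.log(np.clip(pi, 1e-12, 1 - 1e-12))
        log_1mpi = np.log(np.clip(1 - pi, 1e-12, 1 - 1e-12))
        base_prior = float(log_1mpi[cand_idx].sum())
        if yty <= 0:
            # node never responds: keep the empty model
            zeros = np.zeros(p_all)
            return zeros, zeros.copy(), zeros.copy(), zeros.copy()

        for size in range(0, min(len(cand_idx), n) + 1):
            for subset in itertools.combinations(cand_idx, size):
                sub = np.array(subset, dtype=int)
                if size == 0:
                    ssr = yty
                    beta = np.zeros(0)
                    xtx_inv = np.zeros((0, 0))
                else:
                    Xs = X[:, sub]
                    beta, res, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
                    if rank < size:
                        continue  # redundant with a smaller subset
                    resid = y - Xs @ beta
                    ssr = float(resid @ resid)
                    xtx_inv = np.linalg.pinv(Xs.T @ Xs)
                log_m = (0.5 * (n - size) * np.log1p(g)
                         - 0.5 * n * np.log(yty + g * max(ssr, 0.0)))
                log_prior = base_prior + float(
                    (log_pi[sub] - log_1mpi[sub]).sum())
                models.append({"sub": sub, "beta": beta, "ssr": ssr,
                               "xtx_inv": xtx_inv,
                               "log_post": log_m + log_prior})

        log_post = np.array([m["log_post"] for m in models])
        log_post -= log_post.max()
        w = np.exp(log_post)
        keep = w >= self.occam * w.max()
        models = [m for m, k in zip(models, keep) if k]
        w = w[keep]
        w /= w.sum()

        shrink = g / (1.0 + g)
        post_mean = np.zeros(p_all)
        for m, wm in zip(models, w):
            post_mean[m["sub"]] += wm * shrink * m["beta"]
        inclusion = np.zeros(p_all)
        for m, wm in zip(models, w):
            inclusion[m["sub"]] += wm

        # credible intervals from the model-averaged posterior mixture
        counts = rng.multinomial(self.n_draws, w)
        draws = np.zeros((self.n_draws, p_all))
        row = 0
        for m, cnt in zip(models, counts):
            if cnt == 0:
                continue
            q = (yty + g * m["ssr"]) / (1.0 + g)
            sigma2 = q / rng.chisquare(n, size=cnt)
            if m["sub"].size:
                cov = shrink * m["xtx_inv"]
                # symmetric square root (pinv can yield semi-definite cov)
                vals, vecs = np.linalg.eigh(cov)
                sqrt_cov = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
                z = rng.standard_normal((cnt, m["sub"].size))
                samp = (shrink * m["beta"]
                        + np.sqrt(sigma2)[:, None] * (z @ sqrt_cov.T))
                draws[row:row + cnt, m["sub"]] = samp
            row += cnt
        alpha = 0.5 * (1 - self.ci_level)
        lo = np.percentile(draws, 100 * alpha, axis=0)
        hi = np.percentile(draws, 100 * (1 - alpha), axis=0)
        return post_mean, lo, hi, inclusion

    # ------------------------------------------------------------------

    def forward_predict(self, r_xI):
        return forward_predict(self.local_response_, r_xI)

    def edge_table(self) -> pd.DataFrame:
        """Long-format posterior summary (one row per off-diagonal edge)."""
        rows = []
        for tgt in self.nodes_:
            for src in self.nodes_:
                if src == tgt:
                    continue
                rows.append({
                    "source": src, "target": tgt,
                    "mean": self.local_response_.loc[tgt, src],
                    "ci_low": self.ci_low_.loc[tgt, src],
                    "ci_high": self.ci_high_.loc[tgt, src],
                    "inclusion": self.inclusion_.loc[tgt, src],
                    "significant": bool(self.significant_.loc[tgt, src]),
                })
        return pd.DataFrame(rows)


def linear_response_experiments(r: pd.DataFrame, experiments):
    """Noise-free global responses from a known local response matrix.

    ``experiments`` is a list of ``(name, {node: local perturbation
    strength})`` pairs; each column of the returned response matrix is
    ``R = -r^{-1} r_p``.  Returns ``(R, perturbation)`` DataFrames ready
    for :class:`BayesianMRA` — the oracle counterpart of measured
    responses, used to validate inference by exact recovery.
    """
    nodes = list(r.index)
    rinv = np.linalg.inv(r.to_numpy(dtype=float))
    cols, pert = {}, []
    for name, hits in experiments:
        rp = np.zeros(len(nodes))
        for node, strength in hits.items():
            rp[nodes.index(node)] = strength
        cols[name] = -rinv @ rp
        pert.append([1 if n in hits else 0 for n in nodes])
    R = pd.DataFrame(cols, index=nodes)
    P = pd.DataFrame(pert, index=list(cols), columns=nodes)
    return R, P


def infer(R, perturbation=None, prior=None, occam: float = 0.2,
          seed: int | None = 0, **kwargs) -> BayesianMRA:
    """Convenience wrapper returning a fitted :class:`BayesianMRA`."""
    kwargs.setdefault("random_state", seed)
    return BayesianMRA(occam=occam, **kwargs).fit(R, perturbation, prior)


def forward_predict(r, r_xI):
    """Global responses to an inhibitor: ``R_xI = -r^{-1} r_xI``.

    ``r_xI`` holds the local responses of the drug's direct targets (zero
    elsewhere).  Raises on a singular local response matrix.
    """
    if isinstance(r, pd.DataFrame):
        nodes = list(r.index)
        rv = r.to_numpy(dtype=float)
    else:
        rv = np.asarray(r, dtype=float)
        nodes = None
    cond = np.linalg.cond(rv)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"local response matrix is singular or near-singular "
            f"(condition number {cond:.3g})"
        )
    if isinstance(r_xI, (pd.Series, dict)) and nodes is not None:
        vec = pd.Series(r_xI).reindex(nodes).fillna(0.0).to_numpy(dtype=float)
    else:
        vec = np.asarray(r_xI, dtype=float)
    out = -np.linalg.solve(rv, vec)
    if nodes is not None:
        return pd.Series(out, index=nodes, name="R_xI")
    return out


@dataclass
class DriverRanking:
    dpd_node: str
    drivers: list            # (module, local_edge, global_influence), ordered
    normal_weak: bool

    @property
    def primary(self):
        return self.drivers[0][0] if self.drivers else None


def rank_drivers(bmra: BayesianMRA, dpd_node: str) -> DriverRanking:
    """Rank phenotype drivers by their significant DPD in-edges.

    Modules are ordered by |local edge into the DPD node| among the
    significant edges; exact-magnitude ties break by |global influence|
    (the corresponding entry of ``-r^{-1}``).  With no significant
    in-edges the ranking is empty and flagged ``normal_weak``.
    """
    r = bmra.local_response_
    if dpd_node not in r.index:
        raise ValueError(f"unknown DPD node {dpd_node!r}")
    rinv_neg = pd.DataFrame(-np.linalg.inv(r.to_numpy()),
                            index=r.index, columns=r.columns)
    entries = []
    for src in r.columns:
        if src == dpd_node or src.startswith("DPD"):
            continue
        if bool(bmra.significant_.loc[dpd_node, src]):
            local = float(r.loc[dpd_node, src])
            glob = float(rinv_neg.loc[dpd_node, src])
            entries.append((src, local, glob))
    entries.sort(key=lambda e: (-round(abs(e[1]), 10), -abs(e[2]), e[0]))
    return DriverRanking(dpd_node=dpd_node, drivers=entries,
                         normal_weak=not entries)


def cluster_driver_profiles(profiles: pd.DataFrame, n_clusters: int | None = None,
                            cut_height: float | None = None,
                            method: str = "average", metric: str = "euclidean"):
    """Hierarchically cluster per-line DPD in-edge vectors.

    Rows are cell lines, columns signaling modules.  Returns
    ``(labels, Z)`` — flat cluster labels (Series indexed by line) and the
    scipy linkage matrix.  Exactly one of ``n_clusters`` / ``cut_height``
    selects the cut; default is ``n_clusters`` inferred from a 0.5 *
    max-height cut.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 cell lines")
    Z = linkage(profiles.to_numpy(dtype=float), method=method, metric=metric)
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=0.5 * Z[:, 2].max(), criterion="distance")
    return pd.Series(labels, index=profiles.index, name="cluster"), Z
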