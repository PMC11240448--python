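"""Maximal-margin cell-state separation and phenotype scoring.

A linear support-vector machine trained on serum-condition marker profiles
defines a separating hyperplane ``x . n = h``.  The unit normal ``n`` is
the state transition vector (STV): its components rank how much each
analyte contributes to the direction of the state change.  The dynamic
phenotype descriptor (DPD) of a profile is its signed distance to the
hyperplane, ``DPD(x) = x . n - h``, positive on the side of the designated
positive class (cancer, or basal).

The robustness suite perturbs the data (k-fold cross-validation,
multiplicative uniform noise, analyte ablation, random marker subsampling)
and reports classification accuracy distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "StateSeparator",
    "RobustnessConfig",
    "fit_separator",
    "dpd_score",
    "cross_validate",
    "noise_robustness",
    "analyte_ablation",
    "marker_subsample",
]


class StateSeparator(BaseEstimator, ClassifierMixin):
    """Linear-SVM separating hyperplane with signed-distance scoring.

    Parameters
    ----------
    C : float
        SVM cost.  The default 1e6 approximates the hard-margin limit
        (appropriate when the classes are cleanly separable).
    max_iter : int
        Solver iteration cap.  Hard-margin fits on separable data
        converge quickly; the cap only bites on non-separable inputs
        (e.g. heavy noise-injection runs), where an approximate solution
        is acceptable.
    positive_class : label, optional
        Class whose side of the hyperplane scores positive.  Defaults to
        the larger label.
    scale : bool
        Z-score features before fitting (off by default: inputs are
        already control-normalized ratios).

    Attributes
    ----------
    stv_ : ndarray, unit normal to the hyperplane (the STV)
    offset_ : float, hyperplane offset h (the plane is ``x . stv_ = h``)
    analytes_ : feature names when fitted on a DataFrame
    """

    def __init__(self, C: float = 1e6, positive_class=None, scale: bool = False,
                 max_iter: int = 200_000):
        self.C = C
        self.positive_class = positive_class
        self.scale = scale
        self.max_iter = max_iter

    def fit(self, X, y):
        X, feats = _as_array(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x analytes)")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        for c in classes:
            if (y == c).sum() < 1:
                raise ValueError(f"class {c!r} has no samples")

        self.analytes_ = feats
        self.classes_ = classes
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} not among labels")
        self.positive_class_ = pos

        if self.scale:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.std_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.std_

        svm = SVC(kernel="linear", C=self.C, max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svm.fit(Xs, y)
        w = svm.coef_.ravel()
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate separator (zero weight vector)")
        n = w / norm
        h = -svm.intercept_[0] / norm

        # orient so the positive class centroid scores positive
        centroid = Xs[y == pos].mean(axis=0)
        if centroid @ n - h < 0:
            n, h = -n, -h
        self.stv_ = n
        self.offset_ = float(h)
        return self

    def dpd_score(self, X):
        """Signed distance to the hyperplane, ``x . n - h``."""
        check_is_fitted(self, "stv_")
        X, feats = _as_array(X)
        if feats is not None and self.analytes_ is not None:
            if list(feats) != list(self.analytes_):
                raise ValueError("analyte order does not match the fitted hyperplane")
        if X.shape[-1] != self.stv_.shape[0]:
            raise ValueError(
                f"dimension mismatch: {X.shape[-1]} features vs "
                f"{self.stv_.shape[0]} in the hyperplane"
            )
        Xs = (X - self.mean_) / self.std_
        return Xs @ self.stv_ - self.offset_

    decision_function = dpd_score

    def predict(self, X):
        score = self.dpd_score(X)
        neg = [c for c in self.classes_ if c != self.positive_class_][0]
        return np.where(score >= 0, self.positive_class_, neg)


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if isinstance(X, pd.Series):
        return X.to_numpy(dtype=float), list(X.index)
    return np.asarray(X, dtype=float), None


def fit_separator(features, labels, positive_class=None, C: float = 1e6) -> StateSeparator:
    """Fit a maximal-margin separator; returns the fitted estimator."""
    return StateSeparator(C=C, positive_class=positive_class).fit(features, labels)


def dpd_score(x, separator: StateSeparator):
    """DPD score of one profile (or a stack of profiles)."""
    return separator.dpd_score(x)


# --------------------------------------------------------------------------
# Robustness suite
# --------------------------------------------------------------------------


@dataclass
class RobustnessConfig:
    k: int = 8
    nr: float = 0.5
    reps: int = 100
    n_markers: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k-fold CV needs k >= 2")
        if not 0 <= self.nr <= 1:
            raise ValueError("noise ratio nr must lie in [0, 1]")


def _folds(y, k, seed):
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def cross_validate(features, labels, k: int = 8, seed: int = 0,
                   estimator: StateSeparator | None = None):
    """Stratified k-fold CV accuracy; deterministic given the seed."""
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    X, _ = _as_array(features)
    y = np.asarray(labels)
    est = estimator if estimator is not None else StateSeparator()
    accs = []
    for train, test in _folds(y, k, seed).split(X, y):
        model = clone(est).fit(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(accs)), np.asarray(accs)


def noise_robustness(features, labels, nr: float, reps: int = 100,
                     k: int = 8, seed: int = 0) -> dict:
    """Accuracy distribution under multiplicative uniform noise.

    Each repetition perturbs every value ``x`` by an additive draw from
    ``Uniform(-nr*x, nr*x)`` (signal-to-noise ratio 1/nr) and reruns
    k-fold CV.  Returns mean, median, interquartile range and the raw
    accuracies.
    """
    if not 0 <= nr <= 1:
        raise ValueError("noise ratio nr must lie in [0, 1]")
    X, _ = _as_array(features)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    accs = []
    for i in range(reps):
        noisy = X + rng.uniform(-1.0, 1.0, size=X.shape) * nr * X
        acc, _ = cross_validate(noisy, y, k=k, seed=int(rng.integers(2**31 - 1)))
        accs.append(acc)
    accs = np.asarray(accs)
    q1, med, q3 = np.percentile(accs, [25, 50, 75])
    return {"mean": float(accs.mean()), "median": float(med),
            "iqr": float(q3 - q1), "accuracies": accs}


def analyte_ablation(features, labels, k: int = 8, seed: int = 0) -> pd.Series:
    """k-fold CV accuracy after removing each analyte in turn."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"a{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("ablation needs at least 2 analytes")
    y = np.asarray(labels)
    out = {}
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        acc, _ = cross_validate(reduced, y, k=k, seed=seed)
        out[name] = acc
    return pd.Series(out, name="cv_accuracy")


def marker_subsample(features, labels, n_markers, reps: int = 100,
                     k: int = 8, seed: int = 0) -> pd.DataFrame:
    """Accuracy distribution over random marker subsets.

    ``n_markers`` may be an int or a sequence (e.g. ``[10, 20, 30]``);
    markers are sampled without replacement per repetition.  Returns one
    row per (n_markers, repetition).
    """
    X, _ = _as_array(features)
    y = np.asarray(labels)
    sizes = [n_markers] if np.isscalar(n_markers) else list(n_markers)
    rng = np.random.default_rng(seed)
    rows = []
    for m in sizes:
        if m < 1:
            raise ValueError("n_markers must be >= 1")
        if m > X.shape[1]:
            raise ValueError(f"n_markers={m} exceeds panel size {X.shape[1]}")
        for i in range(reps):
            cols = rng.choice(X.shape[1], size=m, replace=False)
            acc, _ = cross_validate(X[:, cols], y, k=k,
                                    seed=int(rng.integers(2**31 - 1)))
            rows.append({"n_markers": m, "rep": i, "accuracy": acc})
    return pd.DataFrame(rows)
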