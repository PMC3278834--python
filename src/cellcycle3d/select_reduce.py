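"""Dimensionality reduction and wrapper feature selection.

Reduction supports PCA, Fisher LDA (output dimension limited to classes − 1)
and classical (Torgerson) metric MDS with the Gower out-of-sample
projection — the out-of-sample rule matters because reduction is applied
inside cross-validation, where test points must be projected with the
training-fold model.  Features are z-scored with training statistics before
any reduction or classification.

Wrapper selection greedily grows (forward) or shrinks (backward) a feature
set, scoring every candidate by stratified cross-validated accuracy of a
classifier — by default the PNN with a fixed kernel width, which needs no
per-subset hyperparameter retuning.  The full trace is recorded and the
chosen set is the best prefix of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted

from .classify import PNNClassifier
from .dataset import PhaseDataset

REDUCTION_METHODS = ("pca", "lda", "mds")
#: Default embedding dimensions: 8 for PCA/MDS (intrinsic dimensionality of
#: the feature cloud), 4 for LDA (classes − 1).
DEFAULT_DIMS = {"pca": 8, "mds": 8, "lda": 4}


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical (Torgerson) metric scaling of the Euclidean distance matrix.

    Fit double-centres the squared-distance matrix and keeps the leading
    positive eigenpairs; ``transform`` projects new points with the Gower
    interpolation formula, which reproduces the training embedding exactly
    for the training points.  On Euclidean data the embedding equals PCA
    scores up to sign.
    """

    def __init__(self, n_components=8):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        if not 1 <= self.n_components <= min(n, X.shape[1]):
            raise ValueError("n_components out of range")
        D2 = pairwise_distances(X, squared=True)
        self.row_means_ = D2.mean(axis=1)
        self.grand_mean_ = float(D2.mean())
        B = -0.5 * (D2 - self.row_means_[None, :] - self.row_means_[:, None] + self.grand_mean_)
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][: self.n_components]
        vals = np.clip(vals[order], 0.0, None)
        self.eigenvalues_ = vals
        self.eigenvectors_ = vecs[:, order]
        self.X_fit_ = X
        self.embedding_ = self.eigenvectors_ * np.sqrt(vals)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        E = pairwise_distances(X, self.X_fit_, squared=True)
        b = -0.5 * (E - E.mean(axis=1, keepdims=True)
                    - self.row_means_[None, :] + self.grand_mean_)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_root = np.where(self.eigenvalues_ > 0, 1.0 / np.sqrt(self.eigenvalues_), 0.0)
        return b @ self.eigenvectors_ * inv_root


def fit_reduce(data: PhaseDataset, method: str = "pca",
               output_dim: int | None = None, seed: int = 0) -> Pipeline:
    """Fit a standardize-then-reduce pipeline on a dataset.

    LDA requires labels and caps the dimension at classes − 1; a singular
    within-class scatter falls back to a shrinkage solver.
    """
    method = method.lower()
    if method not in REDUCTION_METHODS:
        raise ValueError(f"unknown reduction method {method!r}")
    if output_dim is None:
        output_dim = DEFAULT_DIMS[method]
    X = data.X
    if method == "lda":
        y = data.y_codes
        max_dim = len(np.unique(y)) - 1
        if output_dim > max_dim:
            raise ValueError(f"LDA output_dim {output_dim} exceeds classes - 1 = {max_dim}")
        reducer = LinearDiscriminantAnalysis(n_components=output_dim)
    elif method == "pca":
        if output_dim > X.shape[1]:
            raise ValueError("PCA output_dim exceeds input dimension")
        reducer = PCA(n_components=output_dim, random_state=seed)
        y = None
    else:
        if output_dim > X.shape[1]:
            raise ValueError("MDS output_dim exceeds input dimension")
        reducer = ClassicalMDS(n_components=output_dim)
        y = None
    pipe = Pipeline([("scale", StandardScaler()), ("reduce", reducer)])
    try:
        pipe.fit(X, y)
    except np.linalg.LinAlgError:
        if method != "lda":
            raise
        import logging

        logging.getLogger(__name__).warning(
            "singular within-class scatter; using shrinkage LDA")
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("reduce", LinearDiscriminantAnalysis(
                n_components=output_dim, solver="eigen", shrinkage="auto")),
        ])
        pipe.fit(X, y)
    return pipe


# ---------------------------------------------------------------------------
# Greedy wrapper selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Greedy selection history: one (feature set, CV accuracy) per step."""

    steps: list  # [(tuple of feature names, accuracy), ...]
    chosen: tuple
    direction: str

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([acc for _, acc in self.steps])


class GreedyFeatureSelector(TransformerMixin, BaseEstimator):
    """Forward-selection / backward-elimination wrapper around a classifier.

    At each step the feature whose addition (removal) maximizes stratified
    k-fold CV accuracy is added (removed); ties break towards the earliest
    feature in canonical column order.  The search runs to ``n_features``
    and the chosen set is the step with the highest accuracy (earliest on
    ties), so the full trace stays available.  Folds are fixed once per fit
    from the seed, making the search fully reproducible.

    Parameters
    ----------
    estimator : sklearn classifier, optional
        Scoring classifier; default is a PNN with fixed kernel width 1.0
        on z-scored features (no per-subset retuning needed).
    direction : {"forward", "backward"}
    n_features : int, optional
        Where the greedy search stops: maximum set size (forward) or
        minimum set size (backward).  Defaults to all (forward) / 1
        (backward).
    cv : int
        Number of stratified folds.
    """

    def __init__(self, estimator=None, direction="forward", n_features=None,
                 cv=10, random_state=0):
        self.estimator = estimator
        self.direction = direction
        self.n_features = n_features
        self.cv = cv
        self.random_state = random_state

    def _score_subset(self, X, y, cols, splits, base) -> float:
        acc = 0.0
        for tr, te in splits:
            model = clone(base)
            model.fit(X[np.ix_(tr, cols)], y[tr])
            acc += float(np.mean(model.predict(X[np.ix_(te, cols)]) == y[te]))
        return acc / len(splits)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        d = X.shape[1]
        target = self.n_features
        if target is None:
            target = d if self.direction == "forward" else 1
        if not 1 <= target <= d:
            raise ValueError(f"n_features must be in [1, {d}]")
        base = self.estimator
        if base is None:
            base = PNNClassifier(sigma=1.0, random_state=self.random_state)
        base = Pipeline([("scale", StandardScaler()), ("clf", clone(base))])
        cv = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        splits = list(cv.split(X, y))

        current = [] if self.direction == "forward" else list(range(d))
        trace: list[tuple[tuple, float]] = []
        if self.direction == "backward":
            trace.append((tuple(current), self._score_subset(X, y, current, splits, base)))
        while (len(current) < target if self.direction == "forward"
               else len(current) > target):
            best_cols, best_acc = None, -1.0
            if self.direction == "forward":
                candidates = [current + [j] for j in range(d) if j not in current]
            else:
                candidates = [[c for c in current if c != j] for j in current]
            for cols in candidates:
                acc = self._score_subset(X, y, cols, splits, base)
                if acc > best_acc:
                    best_cols, best_acc = cols, acc
            current = best_cols
            trace.append((tuple(current), best_acc))
        self.trace_ = trace
        accs = [acc for _, acc in trace]
        best_step = int(np.argmax(accs))
        self.selected_ = tuple(trace[best_step][0])
        self.support_ = np.zeros(d, dtype=bool)
        self.support_[list(self.selected_)] = True
        self.n_features_in_ = d
        return self

    def transform(self, X):
        check_is_fitted(self)
        return np.asarray(X)[:, self.support_]


def _run_selection(data: PhaseDataset, direction: str, n_features, scorer,
                   folds: int, seed: int) -> SelectionTrace:
    sel = GreedyFeatureSelector(estimator=scorer, direction=direction,
                                n_features=n_features, cv=folds, random_state=seed)
    sel.fit(data.X, data.y_codes)
    names = data.feature_names
    steps = [(tuple(names[j] for j in cols), acc) for cols, acc in sel.trace_]
    chosen = tuple(names[j] for j in sel.selected_)
    return SelectionTrace(steps=steps, chosen=chosen, direction=direction)


def forward_select(data: PhaseDataset, scorer=None, max_features: int | None = None,
                   folds: int = 10, seed: int = 0) -> SelectionTrace:
    """Greedy forward selection scored by CV accuracy (PNN by default)."""
    return _run_selection(data, "forward", max_features, scorer, folds, seed)


def backward_eliminate(data: PhaseDataset, scorer=None, min_features: int = 1,
                       folds: int = 10, seed: int = 0) -> SelectionTrace:
    """Greedy backward elimination, the mirror image of forward selection."""
    return _run_selection(data, "backward", min_features, scorer, folds, seed)
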