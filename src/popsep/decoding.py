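"""Cross-validated logistic-regression category decoding over time.

The decoder is the standard binary logistic model y(phi) = sigma(w^T phi)
on population-vector features, fit by minimising the cross-entropy error
(optionally with a weak ridge penalty; with ~hundreds of neurons and a
few hundred training rows an unpenalised fit can diverge on separable
windows).  Accuracy is measured by stratified k-fold cross-validation
(k = 10 by default) with hard decisions at sigma = 0.5, and the fold
assignment is frozen across windows so that two windows' accuracies
differ only because their population vectors do — the paired
across-window comparisons downstream rely on this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_model import SpikeDataset, TimeWindow
from .popvec import (
    PopulationVectorSet,
    pool_pseudopopulation,
    population_vector_stack,
)


@dataclass
class LoRModel:
    """Fitted logistic decoder: weights, intercept and fit diagnostics."""

    weights: np.ndarray
    intercept: float
    cross_entropy: float      # unpenalised E(w) at the optimum, summed over rows
    converged: bool
    reg: float | None         # ridge strength lambda; None = unpenalised

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(dog | phi) = sigma(w^T phi + b)."""
        return sigmoid(self.decision(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard decisions; ties at exactly 0.5 go to dog (label 1)."""
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class CVResult:
    """k-fold cross-validation accuracy for one window's vectors."""

    mean_accuracy: float
    fold_accuracies: np.ndarray
    k: int
    seed: int
    reg: float | None


@dataclass
class DecodingTimecourse:
    """Mean CV accuracy per sliding-window start, plus per-fold detail."""

    window_starts: np.ndarray
    accuracy: np.ndarray                 # mean over folds, per window
    fold_accuracies: np.ndarray          # (n_windows, k)
    k: int
    seed: int
    reg: float | None
    width: float
    provenance: list[str]

    def __post_init__(self) -> None:
        if not (
            len(self.window_starts) == len(self.accuracy) == len(self.fold_accuracies)
        ):
            raise ValueError("inconsistent time-course lengths")


def sigmoid(a: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function sigma(a) = 1 / (1 + exp(-a))."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def cross_entropy(w: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray) -> float:
    """E(w) = -sum_n [t_n ln sigma + (1 - t_n) ln(1 - sigma)], summed over rows."""
    a = X @ w + intercept
    # log(1 + exp(-|a|)) formulation avoids overflow
    return float(np.sum(np.logaddexp(0.0, a) - y * a))


def fit_logistic(
    X: np.ndarray, y: np.ndarray, reg: float | None = 1.0
) -> LoRModel:
    """Fit the logistic decoder by cross-entropy minimisation.

    ``reg`` is the ridge strength lambda in the objective
    E(w) + (lambda / 2) ||w||^2 (intercept unpenalised); ``reg=None``
    fits the plain cross-entropy objective.  Deterministic given
    (X, y, reg).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the decoder")
    if reg is None:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=10_000)
    else:
        if reg <= 0:
            raise ValueError("reg must be > 0 (or None for no penalty)")
        clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", tol=1e-10, max_iter=10_000)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    converged = bool(np.all(clf.n_iter_ < clf.max_iter))
    return LoRModel(
        weights=w,
        intercept=b,
        cross_entropy=cross_entropy(w, b, X, y),
        converged=converged,
        reg=reg,
    )


def stratified_folds(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seed-shuffled stratified k-fold (train, test) index pairs."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros((len(labels), 1)), labels)]


def cv_accuracy(
    vectors: PopulationVectorSet,
    k: int = 10,
    seed: int = 0,
    reg: float | None = 1.0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Stratified k-fold CV accuracy of the logistic decoder.

    Per fold: fit on the other k-1 folds, count correct hard decisions
    on the held-out images; the mean fraction correct over folds is the
    window's accuracy.  Pass ``folds`` to reuse a frozen fold
    assignment across windows.
    """
    X, y = vectors.matrix, vectors.labels
    if vectors.n_images < k:
        raise ValueError(f"need at least k={k} images, got {vectors.n_images}")
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    accs = np.empty(len(folds))
    for f, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f}: training split lost a class (stratification bug)")
        model = fit_logistic(X[tr], y[tr], reg=reg)
        accs[f] = float(np.mean(model.predict(X[te]) == y[te]))
    return CVResult(
        mean_accuracy=float(accs.mean()),
        fold_accuracies=accs,
        k=len(folds),
        seed=seed,
        reg=reg,
    )


def decoding_timecourse(
    datasets: SpikeDataset | list[SpikeDataset],
    windows: list[TimeWindow],
    k: int = 10,
    seed: int = 0,
    reg: float | None = 1.0,
) -> DecodingTimecourse:
    """CV accuracy of the decoder for each sliding window.

    Accepts one dataset or several (pooled into a pseudo-population per
    window).  The stratified fold assignment is drawn once from ``seed``
    and reused for every window, so the resulting accuracy curve is
    pointwise comparable across windows and across runs with the same
    seed.
    """
    if isinstance(datasets, SpikeDataset):
        datasets = [datasets]
    if not windows:
        raise ValueError("no windows given")
    stacks = [population_vector_stack(d, windows) for d in datasets]
    first = (
        stacks[0][0]
        if len(datasets) == 1
        else pool_pseudopopulation([s[0] for s in stacks])
    )
    folds = stratified_folds(first.labels, k=k, seed=seed)
    accs = np.empty(len(windows))
    fold_accs = np.empty((len(windows), k))
    provenance: list[str] = []
    for wi in range(len(windows)):
        vs = (
            stacks[0][wi]
            if len(datasets) == 1
            else pool_pseudopopulation([s[wi] for s in stacks])
        )
        if wi == 0:
            provenance = list(vs.provenance)
        res = cv_accuracy(vs, k=k, seed=seed, reg=reg, folds=folds)
        accs[wi] = res.mean_accuracy
        fold_accs[wi] = res.fold_accuracies
    return DecodingTimecourse(
        window_starts=np.array([w.start for w in windows]),
        accuracy=accs,
        fold_accuracies=fold_accs,
        k=k,
        seed=seed,
        reg=reg,
        width=windows[0].width,
        provenance=provenance,
    )
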