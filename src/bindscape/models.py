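"""Prediction models for binding behaviour.

* PLSR (partial least squares regression) for continuous targets —
  log10 pocket count, pocket variability, EC entropy — with the component
  count chosen by minimum cross-validated RMSEP (up to 10 components) and
  the reported correlation r taken from leave-one-out predictions.
* SVM classifier for the binary promiscuous/selective call, stratified
  5-fold cross-validation over linear and non-linear kernels.
* CART compound-class tree pruned to the split count (3-10) with lowest
  cross-validated error.

Predictors are standardized to zero mean and unit variance before
fitting; descriptors span several orders of magnitude otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

MAX_COMPONENTS = 10
DEFAULT_KERNELS = ("linear", "rbf", "poly")
SPLIT_RANGE = (3, 10)


@dataclass
class PlsrFit:
    target_name: str
    n_components: int
    feature_names: list[str]
    loadings: np.ndarray        # (n_features, n_components) X-loadings
    weights: np.ndarray         # (n_features, n_components) X-weights
    loo_predictions: np.ndarray
    r: float                    # Pearson r, measured vs LOO-predicted
    rmsep: np.ndarray           # RMSEP over 1..max_components
    n_samples: int
    seed: int = 0


@dataclass
class ClassifierFit:
    kind: str                   # "svm" | "cart"
    cv_error: float
    description: str
    per_setting: dict = field(default_factory=dict)
    seed: int = 0


def _complete_cases(X, y=None):
    X = pd.DataFrame(X)
    mask = ~X.isna().any(axis=1).to_numpy()
    if y is not None:
        y = np.asarray(y, dtype=float)
        mask &= ~np.isnan(y)
    dropped = int((~mask).sum())
    if dropped:
        log.info("dropped %d rows with missing values", dropped)
    Xc = X.loc[mask]
    return (Xc, y[mask] if y is not None else None)


def fit_plsr(X, y, target_name: str = "", max_components: int = MAX_COMPONENTS,
             cv_folds: int = 10, seed: int = 0) -> PlsrFit:
    """PLSR with RMSEP-based component selection and LOO correlation.

    The RMSEP curve over 1..max_components comes from `cv_folds`-fold CV
    (shuffled with `seed`); the component count minimizing it is refit and
    evaluated by leave-one-out prediction to give r.  Rows with missing
    values are dropped; at least 20 complete rows are required.
    """
    X, y = _complete_cases(X, y)
    feature_names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    n = len(Xm)
    if n < 20:
        raise ValueError(f"need >= 20 complete rows, got {n}")
    Xz = StandardScaler().fit_transform(Xm)
    rank = np.linalg.matrix_rank(Xz)
    if rank < 1:
        raise ValueError("predictor matrix has rank 0")
    kmax = int(min(max_components, rank, n - 2))

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rmsep = np.full(kmax, np.nan)
    for k in range(1, kmax + 1):
        sq_err = []
        for train, test in cv.split(Xz):
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(Xz[train], y[train])
            pred = pls.predict(Xz[test]).ravel()
            sq_err.append((pred - y[test]) ** 2)
        rmsep[k - 1] = float(np.sqrt(np.concatenate(sq_err).mean()))
    n_comp = int(np.nanargmin(rmsep)) + 1

    loo_pred = np.empty(n)
    for train, test in LeaveOneOut().split(Xz):
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(Xz[train], y[train])
        loo_pred[test] = pls.predict(Xz[test]).ravel()
    r = float(np.corrcoef(y, loo_pred)[0, 1])

    final = PLSRegression(n_components=n_comp, scale=False).fit(Xz, y)
    loadings = np.asarray(final.x_loadings_).copy()
    weights = np.asarray(final.x_weights_).copy()
    # orient each component so its score correlates positively with y;
    # the underlying NIPALS sign convention is otherwise arbitrary
    yc = y - y.mean()
    scores = np.asarray(final.x_scores_)
    for k in range(n_comp):
        if scores[:, k] @ yc < 0:
            loadings[:, k] *= -1
            weights[:, k] *= -1
    return PlsrFit(target_name, n_comp, feature_names,
                   loadings=loadings,
                   weights=weights,
                   loo_predictions=loo_pred, r=r, rmsep=rmsep,
                   n_samples=n, seed=seed)


def fit_svm_promiscuity(X, labels, kernels=DEFAULT_KERNELS,
                        n_folds: int = 5, seed: int = 0) -> ClassifierFit:
    """Stratified 5-fold CV error of an SVM promiscuity classifier per
    kernel; the best kernel (lowest error) is reported."""
    X = pd.DataFrame(X)
    mask = ~X.isna().any(axis=1).to_numpy()
    y = np.asarray(labels)[mask]
    Xm = X.loc[mask].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both labels must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; {n_folds}-fold "
            "stratified CV infeasible")
    Xz = StandardScaler().fit_transform(Xm)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = {}
    for kernel in kernels:
        wrong = 0
        for train, test in cv.split(Xz, y):
            clf = SVC(kernel=kernel, random_state=seed)
            clf.fit(Xz[train], y[train])
            wrong += int((clf.predict(Xz[test]) != y[test]).sum())
        errors[kernel] = wrong / len(y)
    best = min(errors, key=lambda k: (errors[k], k))
    return ClassifierFit("svm", errors[best], f"kernel={best}",
                         per_setting=errors, seed=seed)


def fit_cart_class(X, classes, split_range=SPLIT_RANGE,
                   n_folds: int = 5, seed: int = 0) -> ClassifierFit:
    """Classification tree pruned within 3-10 splits by cross-validated
    misclassification error.

    A tree with s internal splits has s+1 leaves; candidate trees are
    grown with `max_leaf_nodes` = s+1 for s in `split_range` and the
    lowest-CV-error setting reported.
    """
    X = pd.DataFrame(X)
    mask = ~X.isna().any(axis=1).to_numpy()
    y = np.asarray(classes)[mask]
    Xm = X.loc[mask].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    if np.allclose(Xm, Xm[0]):
        raise ValueError("degenerate (constant) predictor matrix")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = {}
    for splits in range(split_range[0], split_range[1] + 1):
        wrong = 0
        for train, test in cv.split(Xm, y):
            tree = DecisionTreeClassifier(max_leaf_nodes=splits + 1,
                                          random_state=seed)
            tree.fit(Xm[train], y[train])
            wrong += int((tree.predict(Xm[test]) != y[test]).sum())
        errors[splits] = wrong / len(y)
    best = min(errors, key=lambda s: (errors[s], s))
    return ClassifierFit("cart", errors[best], f"splits={best}",
                         per_setting=errors, seed=seed)
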