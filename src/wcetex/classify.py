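"""PCA reduction and repeated stratified cross-validated MLP evaluation.

The evaluation harness mirrors a plain machine-learning protocol:
stratified 10-fold cross-validation repeated 10 times with a standard
multilayer perceptron left at default hyperparameters — one hidden
layer of floor((n_features + n_classes) / 2) logistic units, learning
rate 0.3, momentum 0.2, at most 500 epochs — so that scores reflect the
feature set rather than classifier tuning.  Sensitivity is the recall
of the abnormal class, specificity the recall of the normal class, both
reported as mean +/- std over the repeats.

Standardization and (optional) PCA are fitted on the training rows of
each fold only, so no test information leaks into the projection; a
``pca_scope="global"`` option fits them once on the full table instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier

MLP_LEARNING_RATE = 0.3
MLP_MOMENTUM = 0.2
MLP_EPOCHS = 500


@dataclass
class CVReport:
    """Cross-validation outcome: per-repeat confusion counts and summary rates."""

    sensitivity_mean: float
    sensitivity_std: float
    specificity_mean: float
    specificity_std: float
    per_repeat: list[dict]  # pooled confusion counts and rates per repeat
    folds: int
    repeats: int
    config: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CVReport":
        return cls(**json.loads(text))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def pca_reduce(
    train: np.ndarray, test: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score (train statistics) then project onto the top-k principal axes.

    Returns the reduced train and test tables and the explained-variance
    ratio of the retained components.  The projection is fitted on the
    training rows only; test rows are transformed with the train
    parameters.
    """
    train = np.asarray(train, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if not 1 <= k <= train.shape[1]:
        raise ValueError(f"k must be in [1, {train.shape[1]}], got {k}")
    mu, sd = _standardize_fit(train)
    ztr = (train - mu) / sd
    zte = (test - mu) / sd
    pca = PCA(n_components=k, svd_solver="full")
    rtr = pca.fit_transform(ztr)
    rte = pca.transform(zte) if len(zte) else np.empty((0, k))
    return rtr, rte, pca.explained_variance_ratio_


def default_hidden_units(n_features: int, n_classes: int = 2) -> int:
    return (n_features + n_classes) // 2


def train_mlp(X: np.ndarray, y: np.ndarray, seed: int = 0, hidden: int | None = None) -> MLPClassifier:
    """Fit the default multilayer perceptron on a (standardized) table.

    Deterministic for a fixed seed.  Raises on single-class input.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if hidden is None:
        hidden = default_hidden_units(X.shape[1], classes.size)
    model = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=MLP_LEARNING_RATE,
        momentum=MLP_MOMENTUM,
        max_iter=MLP_EPOCHS,
        n_iter_no_change=MLP_EPOCHS,  # fixed epoch budget, no plateau stop
        random_state=int(seed) % (2**31 - 1),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _rates(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    se = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    sp = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return se, sp


def repeated_cv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    pca_k: int | None = None,
    pca_scope: str = "fold",
    std_over: str = "repeats",
    groups: np.ndarray | None = None,
    config: dict | None = None,
) -> CVReport:
    """Repeated stratified k-fold MLP evaluation of a labeled feature table.

    ``y`` holds 0 for normal and 1 for abnormal.  Each repeat draws a
    fresh stratified partition from a seed derived from the master seed;
    within a repeat every frame is tested exactly once, and per-repeat
    rates pool the fold confusion counts.  ``pca_k`` enables PCA to k
    components, fitted per training fold (``pca_scope="fold"``) or once
    on the whole table (``"global"``).  ``groups`` switches to
    group-aware stratified folding (e.g. patient ids).  ``std_over``
    selects the spread convention: over the repeat means (default) or
    over all individual folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0 (normal) or 1 (abnormal)")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n_min = min(np.bincount(y))
    if n_min < folds:
        raise ValueError(f"smallest class has {n_min} frames; needs >= {folds} for {folds}-fold CV")
    if pca_scope not in ("fold", "global"):
        raise ValueError(f"unknown pca_scope {pca_scope!r}")
    if std_over not in ("repeats", "folds"):
        raise ValueError(f"unknown std_over {std_over!r}")

    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=(repeats, folds + 1))

    per_repeat: list[dict] = []
    fold_se: list[float] = []
    fold_sp: list[float] = []

    Xg = X
    if pca_scope == "global" and pca_k is not None:
        Xg, _, _ = pca_reduce(X, X, pca_k)

    for r in range(repeats):
        splitter_seed = int(run_seeds[r, 0])
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=splitter_seed)
            split = cv.split(Xg, y, groups)
        else:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=splitter_seed)
            split = cv.split(Xg, y)
        tp = fn = tn = fp = 0
        for f, (tr_idx, te_idx) in enumerate(split):
            Xtr, Xte = Xg[tr_idx], Xg[te_idx]
            ytr, yte = y[tr_idx], y[te_idx]
            if pca_scope == "fold" and pca_k is not None:
                Xtr, Xte, _ = pca_reduce(Xtr, Xte, pca_k)
            else:
                mu, sd = _standardize_fit(Xtr)
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            model = train_mlp(Xtr, ytr, seed=int(run_seeds[r, f + 1]))
            pred = model.predict(Xte)
            tp_f = int(((pred == 1) & (yte == 1)).sum())
            fn_f = int(((pred == 0) & (yte == 1)).sum())
            tn_f = int(((pred == 0) & (yte == 0)).sum())
            fp_f = int(((pred == 1) & (yte == 0)).sum())
            tp, fn, tn, fp = tp + tp_f, fn + fn_f, tn + tn_f, fp + fp_f
            se_f, sp_f = _rates(tp_f, fn_f, tn_f, fp_f)
            fold_se.append(se_f)
            fold_sp.append(sp_f)
        se, sp = _rates(tp, fn, tn, fp)
        per_repeat.append(
            {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "sensitivity": se, "specificity": sp}
        )

    rep_se = np.array([r["sensitivity"] for r in per_repeat])
    rep_sp = np.array([r["specificity"] for r in per_repeat])
    if std_over == "repeats":
        se_std = float(rep_se.std(ddof=1)) if repeats > 1 else 0.0
        sp_std = float(rep_sp.std(ddof=1)) if repeats > 1 else 0.0
    else:
        se_std = float(np.nanstd(fold_se, ddof=1))
        sp_std = float(np.nanstd(fold_sp, ddof=1))

    echo = dict(config or {})
    echo.update(
        {"pca_k": pca_k, "pca_scope": pca_scope, "seed": int(seed), "std_over": std_over}
    )
    return CVReport(
        sensitivity_mean=float(rep_se.mean()),
        sensitivity_std=se_std,
        specificity_mean=float(rep_sp.mean()),
        specificity_std=sp_std,
        per_repeat=per_repeat,
        folds=folds,
        repeats=repeats,
        config=echo,
    )
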