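"""Cross-validated feed-forward classifier harness shared by all stages.

Every classifier stage in the pipeline (outcome, tissue, DPI, IC50) uses the
same contract: a standardized multi-layer perceptron trained under
stratified k-fold cross-validation, reporting out-of-fold ROC-AUC per fold,
and a final model refit on all rows exposing ``predict_proba``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import StratificationError
from .types import CVReport, GeneRanking

#: Default architecture: two hidden layers, rectifier activations, L2
#: weight decay, full-batch L-BFGS optimisation (deterministic and robust at
#: desk-scale sample sizes where minibatch SGD is noisy).
DEFAULT_ARCH = {
    "hidden": (64, 32),
    "alpha": 1.0,
    "max_iter": 200,
    "solver": "lbfgs",
}


def make_classifier(arch: Optional[dict], seed: int) -> Pipeline:
    """Standardizer + MLP pipeline configured from an ``arch`` dict."""
    cfg = dict(DEFAULT_ARCH)
    if arch:
        cfg.update(arch)
    kwargs = {}
    if cfg["solver"] == "adam":
        kwargs.update(early_stopping=True, validation_fraction=0.1, n_iter_no_change=10)
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(cfg["hidden"]),
        activation="relu",
        alpha=cfg["alpha"],
        max_iter=cfg["max_iter"],
        solver=cfg["solver"],
        random_state=seed,
        **kwargs,
    )
    return Pipeline([("scale", StandardScaler()), ("mlp", mlp)])


def cross_validated_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 5,
    arch: Optional[dict] = None,
    seed: int = 0,
):
    """Train with stratified k-fold CV; return (refit model, CVReport).

    ``X``: rows are samples (index = sample ids), columns features.
    ``y``: binary labels aligned on the same index.
    """
    X = X.loc[y.index]
    yv = y.to_numpy()
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) != 2:
        raise StratificationError(
            f"need exactly 2 classes, got {list(classes)}"
        )
    if counts.min() < folds:
        raise StratificationError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"{folds} folds with both classes present"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xv = X.to_numpy(dtype=float)
    fold_aucs = []
    assignment = np.empty(len(yv), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(Xv, yv)):
        model = make_classifier(arch, seed + fold)
        model.fit(Xv[tr], yv[tr])
        prob = model.predict_proba(Xv[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(yv[te], prob)))
        assignment[te] = fold
    final = make_classifier(arch, seed)
    final.fit(Xv, yv)
    report = CVReport(
        fold_aucs=fold_aucs,
        fold_assignments=pd.Series(assignment, index=X.index, name="fold"),
    )
    return final, report


def permutation_importance_ranking(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 5,
    arch: Optional[dict] = None,
    seed: int = 0,
    n_repeats: int = 3,
    columns: Optional[list] = None,
    method_tag: str = "permutation",
) -> GeneRanking:
    """Model-agnostic importance: mean held-out log-loss increase when a
    feature is permuted, averaged over folds.

    Log loss (rather than AUC) is the permutation score because it keeps
    responding to shrinking prediction margins even when the ranking metric
    is saturated — with many redundant informative features, AUC can sit at
    1.0 while each feature still tightens every margin.  ``columns``
    restricts the ranking to a feature subset (e.g. the expression block of
    a concatenated feature vector).  Features with non-positive mean
    importance are excluded; ties broken by feature id for determinism.
    """
    X = X.loc[y.index]
    yv = y.to_numpy()
    cols = list(columns) if columns is not None else list(X.columns)
    col_idx = [X.columns.get_loc(c) for c in cols]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xv = X.to_numpy(dtype=float)
    importances = np.zeros(len(cols))
    for fold, (tr, te) in enumerate(skf.split(Xv, yv)):
        model = make_classifier(arch, seed + fold)
        model.fit(Xv[tr], yv[tr])
        rng = np.random.default_rng(seed + 1000 * fold)
        base = log_loss(yv[te], model.predict_proba(Xv[te])[:, 1], labels=[0, 1])
        Xte = Xv[te]
        for ci, c in enumerate(col_idx):
            drops = []
            for r in range(n_repeats):
                perm = Xte.copy()
                perm[:, c] = rng.permutation(perm[:, c])
                loss = log_loss(
                    yv[te], model.predict_proba(perm)[:, 1], labels=[0, 1]
                )
                drops.append(loss - base)
            importances[ci] += np.mean(drops)
    importances /= folds
    entries = [
        (c, float(imp))
        for c, imp in sorted(
            zip(cols, importances), key=lambda t: (-t[1], t[0])
        )
        if imp > 0
    ]
    return GeneRanking(entries=entries, method=method_tag)
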