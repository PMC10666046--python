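"""Stage 2 — tumor/normal filter.

A feed-forward classifier separates tumor from normal tissue on expression;
genes are ranked by held-out permutation importance (model-agnostic, works
for any classifier), a selector cuts the ranking to a discriminative gene
set, and the stage-1 prognostic list is intersected with it, preserving
prognostic order — leaving genes that both predict poor outcome and
distinguish tumor from healthy tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError
from .models import cross_validated_classifier, permutation_importance_ranking
from .types import ExpressionMatrix, GeneRanking


def _tissue_to_binary(labels: pd.Series) -> pd.Series:
    vals = set(labels.unique())
    if not vals <= {"tumor", "normal"}:
        raise DataError(f"tissue labels must be 'tumor'/'normal', got {sorted(vals)}")
    if len(vals) < 2:
        raise DataError("both tissue classes must be non-empty")
    return (labels == "tumor").astype(int)


def train_tissue_classifier(
    expression: ExpressionMatrix,
    labels: pd.Series,
    folds: int = 5,
    arch: Optional[dict] = None,
    seed: int = 0,
):
    """Cross-validated tumor-vs-normal classifier; returns (model, CVReport)."""
    y = _tissue_to_binary(labels)
    missing = [s for s in y.index if s not in expression.samples]
    if missing:
        raise DataError(f"samples without expression: {missing[:5]}...")
    # log1p stabilises the heavy right tail of expression before scaling
    X = np.log1p(expression.values.T.loc[y.index])
    return cross_validated_classifier(X, y, folds=folds, arch=arch, seed=seed)


def rank_tissue_genes(
    expression: ExpressionMatrix,
    labels: pd.Series,
    folds: int = 5,
    arch: Optional[dict] = None,
    seed: int = 0,
    n_repeats: int = 3,
) -> GeneRanking:
    """Permutation-importance gene ranking for the tissue classifier."""
    y = _tissue_to_binary(labels)
    X = np.log1p(expression.values.T.loc[y.index])
    return permutation_importance_ranking(
        X, y, folds=folds, arch=arch, seed=seed, n_repeats=n_repeats,
        method_tag="permutation/tissue",
    )


@dataclass
class GeneSelection:
    """A gene set plus the selector that produced it."""

    genes: frozenset
    selector: dict


def select_discriminative_genes(ranking: GeneRanking, selector: dict) -> GeneSelection:
    """Cut a ranking to a gene set by ``{"top_k": n}`` or ``{"min_importance": t}``."""
    if not ranking.entries:
        raise ArgumentError("ranking must be non-empty")
    if set(selector) == {"top_k"}:
        k = int(selector["top_k"])
        if k < 1:
            raise ArgumentError("top_k must be >= 1")
        chosen = frozenset(ranking.top(k))
    elif set(selector) == {"min_importance"}:
        tau = float(selector["min_importance"])
        chosen = frozenset(g for g, imp in ranking.entries if imp >= tau)
    else:
        raise ArgumentError(
            "selector must be {'top_k': n} or {'min_importance': t}"
        )
    if not chosen:
        warnings.warn(f"selector {selector} passed zero genes")
    return GeneSelection(genes=chosen, selector=dict(selector))


def intersect_targets(prognostic: list, discriminative) -> list:
    """Subsequence of the prognostic list restricted to discriminative genes.

    Order of the prognostic list is preserved; the result is a subset of
    both inputs.
    """
    if isinstance(discriminative, GeneSelection):
        discriminative = discriminative.genes
    members = set(discriminative)
    return [g for g in prognostic if g in members]
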