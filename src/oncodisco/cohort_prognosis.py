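"""Stage 1 — prognostic target identification.

Expression is normalized against a housekeeping reference gene, survival
endpoints (OS, PFI) are binarized at the cohort median, a feed-forward
classifier is cross-validated to confirm predictive signal, the cohort can
be enlarged with synthetic patients from a tabular generative model, genes
are ranked by L1-regularized (Lasso) linear regression against the binary
outcome, and the per-endpoint rankings are merged into one candidate list.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .errors import ArgumentError, DataError
from .models import cross_validated_classifier
from .types import CVReport, ExpressionMatrix, GeneRanking, OutcomeLabels

_ENDPOINT_COLUMNS = {"OS": "os_time", "PFI": "pfi_time"}


def normalize_expression(
    matrix: ExpressionMatrix, reference_gene: str
) -> ExpressionMatrix:
    """Divide each sample's expression by that sample's reference-gene level.

    The reference ("housekeeping") row becomes all ones; the operation is
    idempotent.  Raises :class:`DataError` naming the offending samples if
    the reference gene is absent or not strictly positive anywhere.
    """
    values = matrix.values
    if reference_gene not in values.index:
        raise DataError(f"reference gene {reference_gene!r} not in matrix")
    ref = values.loc[reference_gene]
    bad = ref.index[~(ref > 0)].tolist()
    if bad:
        raise DataError(
            f"reference gene {reference_gene!r} non-positive in samples: {bad}"
        )
    return ExpressionMatrix(values.div(ref, axis=1), normalized_to=reference_gene)


def binarize_outcome(
    clinical: pd.DataFrame, endpoint: str, tie_rule: str = "below"
) -> OutcomeLabels:
    """Label patients by whether their endpoint time surpasses the cohort median.

    Label 1 iff time strictly greater than the median of all included
    patients' times; times exactly at the median go to class 0 under the
    default ``tie_rule="below"`` (or class 1 under ``"above"``).
    """
    if endpoint not in _ENDPOINT_COLUMNS:
        raise ArgumentError(f"endpoint must be one of {sorted(_ENDPOINT_COLUMNS)}")
    if tie_rule not in ("below", "above"):
        raise ArgumentError("tie_rule must be 'below' or 'above'")
    col = _ENDPOINT_COLUMNS[endpoint]
    times = pd.to_numeric(clinical[col], errors="coerce")
    mask = np.isfinite(times)
    if mask.sum() < 2:
        raise DataError(f"need >= 2 patients with finite {endpoint} times")
    times = times[mask]
    ids = clinical.loc[mask.to_numpy(), "patient_id"]
    median = float(np.median(times))
    if times.nunique() == 1:
        raise DataError(f"all {endpoint} times identical ({median}); labels degenerate")
    above = times.to_numpy() > median
    at = times.to_numpy() == median
    labels = np.where(above, 1, np.where(at, 1 if tie_rule == "above" else 0, 0))
    if labels.min() == labels.max():
        raise DataError(
            f"median split of {endpoint} produced a single class; "
            "adjust tie_rule or check the time distribution"
        )
    return OutcomeLabels(
        labels=pd.Series(labels, index=ids.to_numpy(), name=endpoint),
        endpoint=endpoint,
        median_used=median,
    )


def train_outcome_classifier(
    features: ExpressionMatrix,
    labels: OutcomeLabels,
    folds: int = 5,
    arch: Optional[dict] = None,
    seed: int = 0,
):
    """Cross-validated feed-forward classifier of the binarized outcome.

    Returns ``(model, CVReport)``; the model exposes ``predict_proba`` on
    gene-expression rows ordered like ``features.genes``.
    """
    missing = [p for p in labels.labels.index if p not in features.samples]
    if missing:
        raise DataError(f"patients without expression: {missing[:5]}...")
    # log1p stabilises the heavy right tail of expression before scaling
    X = np.log1p(features.values.T.loc[labels.labels.index])
    return cross_validated_classifier(X, labels.labels, folds=folds, arch=arch, seed=seed)


# ---------------------------------------------------------------------------
# Cohort augmentation (tabular generative model)
# ---------------------------------------------------------------------------

def _fit_copula(block: pd.DataFrame):
    """Gaussian copula of one class block: normal scores + correlation +
    empirical-quantile marginals (samples stay within observed ranges)."""
    from scipy import stats

    n, p = block.shape
    arr = block.to_numpy(dtype=float)
    # rank -> uniform -> normal scores (average ranks keep ties stable)
    u = (stats.rankdata(arr, axis=0) - 0.5) / n
    z = stats.norm.ppf(u)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z, rowvar=False)  # constant columns yield NaN rows
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    # nearest PSD guard
    w, v = np.linalg.eigh(corr)
    corr = (v * np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    return arr, corr


def _sample_copula(arr: np.ndarray, corr: np.ndarray, n: int, rng) -> np.ndarray:
    from scipy import stats

    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, corr.shape[0])) @ L.T
    u = stats.norm.cdf(z)
    out = np.empty_like(z)
    for j in range(arr.shape[1]):
        out[:, j] = np.quantile(arr[:, j], u[:, j])
    return out


def augment_with_gan(
    table: pd.DataFrame,
    n_synthetic: int,
    seed: int = 0,
    backend: str = "copula",
    label_col: str = "label",
) -> pd.DataFrame:
    """Append synthetic patient rows drawn from a tabular generative model.

    The default backend is a per-class Gaussian copula: marginals are
    empirical quantiles (synthetic values never leave the observed range of
    each column), the dependence structure is the normal-scores correlation,
    and the label column is preserved as categorical by fitting one copula
    per class and sampling labels at the observed class frequencies.
    Synthetic rows carry ``synthetic=True``; real rows ``False``.
    ``n_synthetic=0`` returns the input unchanged.
    """
    if n_synthetic < 0:
        raise ArgumentError("n_synthetic must be >= 0")
    if backend not in ("copula",):
        raise ArgumentError(
            f"backend {backend!r} unavailable; the built-in generative backend is 'copula'"
        )
    if n_synthetic == 0:
        return table.copy()
    if len(table) < 50:
        raise ArgumentError("augmentation needs a table with >= 50 rows")
    if label_col not in table.columns:
        raise DataError(f"label column {label_col!r} missing")
    feat_cols = [c for c in table.columns if c != label_col]
    if not all(np.issubdtype(table[c].dtype, np.number) for c in feat_cols):
        raise DataError("all feature columns must be numeric")

    rng = np.random.default_rng(seed)
    labels = table[label_col]
    classes, counts = np.unique(labels, return_counts=True)
    # proportional allocation, remainder to the largest class
    alloc = np.floor(n_synthetic * counts / counts.sum()).astype(int)
    alloc[np.argmax(counts)] += n_synthetic - alloc.sum()

    pieces = []
    for cls, n_cls in zip(classes, alloc):
        if n_cls == 0:
            continue
        block = table.loc[labels == cls, feat_cols]
        arr, corr = _fit_copula(block)
        sampled = _sample_copula(arr, corr, n_cls, rng)
        piece = pd.DataFrame(sampled, columns=feat_cols)
        piece[label_col] = cls
        pieces.append(piece)

    real = table.copy()
    real["synthetic"] = False
    synth = pd.concat(pieces, ignore_index=True)
    synth["synthetic"] = True
    out = pd.concat([real, synth], ignore_index=True)
    out[label_col] = out[label_col].astype(table[label_col].dtype)
    return out


# ---------------------------------------------------------------------------
# Lasso feature ranking
# ---------------------------------------------------------------------------

def rank_features_lasso(
    features,
    labels,
    folds: int = 5,
    seed: int = 0,
) -> GeneRanking:
    """Rank genes by |coefficient| of a CV-tuned Lasso linear regression on
    the binary outcome.

    ``features`` may be an :class:`ExpressionMatrix` (genes x patients) or a
    DataFrame of rows x genes; ``labels`` an :class:`OutcomeLabels` or a
    binary Series aligned on row ids.  Zero-variance genes are dropped
    before fitting; genes with zero coefficient are excluded from the
    ranking (an all-zero fit yields an empty ranking with a warning).
    """
    if isinstance(features, ExpressionMatrix):
        X = np.log1p(features.values.T)
    else:
        X = features
    y = labels.labels if isinstance(labels, OutcomeLabels) else labels
    X = X.loc[y.index]
    variances = X.var(axis=0)
    keep = variances[variances > 0].index
    X = X[keep]
    if X.shape[1] == 0:
        warnings.warn("no non-constant genes; empty ranking")
        return GeneRanking(entries=[], method="lasso")
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    yv = y.to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=40, max_iter=5000, random_state=seed)
    model.fit(Xs, yv)
    coefs = model.coef_
    entries = [
        (g, float(abs(c)))
        for g, c in sorted(zip(keep, coefs), key=lambda t: (-abs(t[1]), t[0]))
        if c != 0.0
    ]
    if not entries:
        warnings.warn("Lasso selected no genes; empty ranking")
    return GeneRanking(entries=entries, method="lasso")


def merge_gene_lists(
    ranking_os: GeneRanking, ranking_pfi: GeneRanking, top_k: int
) -> list:
    """Union of the top-k genes of two endpoint rankings.

    Ordered by best (minimum) 1-based rank across the two lists; ties broken
    by higher summed importance, then lexicographically by gene id.
    """
    if top_k < 1:
        raise ArgumentError("top_k must be >= 1")
    rank_os = {g: i + 1 for i, g in enumerate(ranking_os.genes)}
    rank_pfi = {g: i + 1 for i, g in enumerate(ranking_pfi.genes)}
    imp_os = dict(ranking_os.entries)
    imp_pfi = dict(ranking_pfi.entries)
    candidates = set(ranking_os.top(top_k)) | set(ranking_pfi.top(top_k))

    def key(g):
        best = min(rank_os.get(g, np.inf), rank_pfi.get(g, np.inf))
        total = imp_os.get(g, 0.0) + imp_pfi.get(g, 0.0)
        return (best, -total, g)

    return sorted(candidates, key=key)
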