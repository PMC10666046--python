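"""Stage 5 — preclinical cell-line experiment emulation.

A classifier of IC50-test success is trained on (cell-line expression ⊕
compound vector) rows, with a permutation-importance ranking restricted to
the expression block.  Candidate inhibitors are screened across the whole
line panel to give a molecules x lines probability matrix; molecules must
exceed a probability threshold on every required target line, large hits
can be decomposed into fragments (BRICS bond-breaking rules), and the
selectivity filter ranks survivors by how few lines they hit above the
threshold (fewest = most selective).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS

from .embeddings import KmerEmbeddingTable, embed_compound
from .errors import ArgumentError, DataError, SmilesParseError
from .models import cross_validated_classifier, permutation_importance_ranking
from .types import CellLineProfile, CompoundRecord, PredictionMatrix


def assemble_cell_dataset(
    lines: Sequence[CellLineProfile],
    sensitivity: pd.DataFrame,
    compound_vectors: dict,
):
    """One labeled row per sensitivity record: line expression ⊕ compound vector.

    Records whose line profile or compound vector is unavailable are
    excluded and reported in a warning.  Returns ``(X, y, gene_columns)``
    where ``X`` is a DataFrame whose first columns are the panel's genes and
    remaining columns the compound-vector components.
    """
    line_by_id = {ln.id: ln for ln in lines}
    if sensitivity.empty:
        return pd.DataFrame(), pd.Series(dtype=int), []
    gene_cols = list(next(iter(line_by_id.values())).expression.index)
    dim = len(next(iter(compound_vectors.values()))) if compound_vectors else 0
    vec_cols = [f"cvec_{i}" for i in range(dim)]
    rows, labels, dropped = [], [], 0
    for rec in sensitivity.itertuples(index=False):
        line = line_by_id.get(rec.line_id)
        vec = compound_vectors.get(rec.compound_id)
        if line is None or vec is None:
            dropped += 1
            continue
        rows.append(np.concatenate([line.expression.to_numpy(dtype=float), vec]))
        labels.append(int(rec.success))
    if dropped:
        warnings.warn(f"{dropped} sensitivity records unresolvable; excluded")
    X = pd.DataFrame(rows, columns=gene_cols + vec_cols)
    y = pd.Series(labels, index=X.index, name="success")
    return X, y, gene_cols


def train_ic50_model(
    X: pd.DataFrame,
    y: pd.Series,
    gene_cols: Sequence[str],
    arch: Optional[dict] = None,
    folds: int = 5,
    seed: int = 0,
    n_repeats: int = 2,
):
    """Cross-validated IC50-success classifier + expression-block importance.

    Returns ``(model, CVReport, GeneRanking)``; the ranking covers only the
    expression features, never the compound-vector block.
    """
    if y.nunique() != 2:
        raise DataError("both success classes must be present")
    model, report = cross_validated_classifier(X, y, folds=folds, arch=arch, seed=seed)
    ranking = permutation_importance_ranking(
        X, y, folds=folds, arch=arch, seed=seed, n_repeats=n_repeats,
        columns=list(gene_cols), method_tag="permutation/ic50",
    )
    return model, report, ranking


def predict_matrix(
    model,
    candidates: Sequence[CompoundRecord],
    lines: Sequence[CellLineProfile],
    compound_table: KmerEmbeddingTable,
) -> PredictionMatrix:
    """Probability of IC50 success for every (candidate, line) pair.

    Candidates whose SMILES cannot be embedded are dropped with a warning.
    """
    vecs, dropped = {}, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in candidates:
            try:
                vecs[rec.id] = embed_compound(rec.smiles, compound_table)
            except SmilesParseError:
                dropped.append(rec.id)
    if dropped:
        warnings.warn(f"{len(dropped)} candidates not embeddable; rows dropped")
    line_ids = [ln.id for ln in lines]
    expr = np.vstack([ln.expression.to_numpy(dtype=float) for ln in lines])
    mol_ids = list(vecs)
    probs = np.empty((len(mol_ids), len(line_ids)))
    for i, mid in enumerate(mol_ids):
        feats = np.hstack([expr, np.tile(vecs[mid], (len(line_ids), 1))])
        probs[i] = model.predict_proba(feats)[:, 1]
    return PredictionMatrix(
        probabilities=pd.DataFrame(probs, index=mol_ids, columns=line_ids)
    )


def filter_by_target_lines(
    matrix: PredictionMatrix,
    target_lines: Sequence[str],
    threshold: float = 0.9,
) -> list:
    """Molecules whose probability strictly exceeds ``threshold`` on every
    named target line (matrix row order preserved)."""
    probs = matrix.probabilities
    unknown = [ln for ln in target_lines if ln not in probs.columns]
    if unknown:
        raise ArgumentError(f"unknown cell lines: {unknown}")
    if not target_lines:
        return list(probs.index)
    mask = (probs[list(target_lines)] > threshold).all(axis=1)
    return list(probs.index[mask])


def decompose_molecule(smiles: str, rule_set: str = "brics") -> list:
    """Fragment a molecule at BRICS bond-breaking sites.

    Fragments are canonicalized, stripped of attachment-point dummy atoms
    and deduplicated (sorted); a molecule with no breakable bond returns
    itself (canonical form).  Decomposition is idempotent on its own
    fragments.
    """
    if rule_set != "brics":
        raise ArgumentError(f"unknown rule set {rule_set!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    raw = list(BRICS.BRICSDecompose(mol))
    frags = set()
    for frag_smiles in raw:
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            continue
        editable = Chem.RWMol(frag)
        for atom in sorted(
            (a.GetIdx() for a in editable.GetAtoms() if a.GetAtomicNum() == 0),
            reverse=True,
        ):
            editable.RemoveAtom(atom)
        if editable.GetNumAtoms() == 0:
            continue
        try:
            stripped = editable.GetMol()
            Chem.SanitizeMol(stripped)
        except Exception:
            continue
        frags.add(Chem.MolToSmiles(stripped))
    frags.discard("")
    if not frags:
        return [Chem.MolToSmiles(mol)]
    return sorted(frags)


def selectivity_filter(
    matrix: PredictionMatrix,
    threshold: float,
    required_lines: Sequence[str],
    top_n: int,
) -> list:
    """Rank molecules passing the target-line filter by selectivity.

    Selectivity = the count of ALL lines with probability > ``threshold``
    (fewest first); ties broken by lower mean probability over off-target
    lines, then molecule id.  Returns the ``top_n`` most selective.
    """
    if top_n < 0:
        raise ArgumentError("top_n must be >= 0")
    passing = filter_by_target_lines(matrix, required_lines, threshold)
    probs = matrix.probabilities
    off_cols = [c for c in probs.columns if c not in set(required_lines)]

    def key(mol):
        row = probs.loc[mol]
        n_hit = int((row > threshold).sum())
        off_mean = float(row[off_cols].mean()) if off_cols else 0.0
        return (n_hit, off_mean, mol)

    return sorted(passing, key=key)[:top_n]
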