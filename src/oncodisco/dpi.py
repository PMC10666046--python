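"""Stage 4 — drug-protein interaction (DPI) prediction.

The labeled dataset combines a positive interaction list with
"quartile negatives": (compound, protein) pairs whose interaction score in a
STITCH-like score table falls at or below the first quartile of the full
score distribution, restricted to the most frequently scored compounds.
Features are the concatenation of the protein and compound sum-embeddings
(200-dimensional at the default d=100).  A cross-validated feed-forward
classifier yields interaction probabilities used to screen a compound
library against target proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import KmerEmbeddingTable, embed_compound, embed_protein
from .errors import ArgumentError, DataError, SmilesParseError
from .models import cross_validated_classifier
from .types import CompoundRecord, ProteinRecord


def five_number_summary(values) -> dict:
    """min/Q1/median/Q3/max with linear-interpolation ("type 7") quantiles."""
    v = np.asarray(values, dtype=float)
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def positive_overlap_summary(
    scores: pd.DataFrame, positives: Sequence[tuple]
) -> dict:
    """Compare the score distribution of known-positive pairs with all scores.

    Returns five-number summaries for both groups and an ``overlap`` flag:
    True iff the minimum positive score lies at or below the upper whisker
    (Q3 + 1.5 IQR) of the full distribution — i.e. the positives are NOT a
    clean upper outlier of the bulk.
    """
    keyed = set(zip(scores["protein_id"], scores["compound_id"]))
    positives = set(positives)
    missing = sorted(positives - keyed)
    if missing:
        warnings.warn(
            f"{len(missing)} positive pairs absent from the score table; excluded"
        )
        positives = positives - set(missing)
    mask = [
        (p, c) in positives for p, c in zip(scores["protein_id"], scores["compound_id"])
    ]
    pos_scores = scores.loc[mask, "score"].to_numpy()
    all_scores = scores["score"].to_numpy()
    if len(pos_scores) < 4 or len(all_scores) < 4:
        raise ArgumentError("need >= 4 scores in each group")
    pos = five_number_summary(pos_scores)
    full = five_number_summary(all_scores)
    whisker = full["q3"] + 1.5 * (full["q3"] - full["q1"])
    return {
        "positive": pos,
        "all": full,
        "upper_whisker": float(whisker),
        "overlap": bool(pos["min"] <= whisker),
        "n_positive": int(len(pos_scores)),
        "n_all": int(len(all_scores)),
        "missing_positives": missing,
    }


@dataclass
class DPIDataset:
    """Labeled (protein vector, compound vector) rows with provenance."""

    frame: pd.DataFrame  # protein_id, compound_id, label, provenance
    features: np.ndarray  # rows x 2d
    vector_dim: int  # d (per entity)

    def __post_init__(self) -> None:
        pos = set(
            zip(*self.frame.loc[self.frame.label == 1, ["protein_id", "compound_id"]]
                .to_numpy().T)
        ) if (self.frame.label == 1).any() else set()
        neg = set(
            zip(*self.frame.loc[self.frame.label == 0, ["protein_id", "compound_id"]]
                .to_numpy().T)
        ) if (self.frame.label == 0).any() else set()
        if pos & neg:
            raise DataError("positive and negative pairs overlap")
        if not (
            (self.frame.loc[self.frame.label == 1, "provenance"] == "positive_list").all()
            and (self.frame.loc[self.frame.label == 0, "provenance"] == "quartile_negative").all()
        ):
            raise DataError("labels inconsistent with provenance")


def quartile_negative_pairs(
    scores: pd.DataFrame,
    positives: set,
    max_compounds: int = 50000,
) -> pd.DataFrame:
    """Pairs with score <= Q1 of the full distribution, restricted to the
    ``max_compounds`` compounds with the most scored interactions (ties by
    compound id), excluding any pair in the positive list."""
    q1 = float(np.quantile(scores["score"], 0.25))
    counts = scores["compound_id"].value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    allowed = set(order[:max_compounds])
    low = scores[
        (scores["score"] <= q1) & scores["compound_id"].isin(allowed)
    ]
    keep = [
        (p, c) not in positives
        for p, c in zip(low["protein_id"], low["compound_id"])
    ]
    return low.loc[keep]


def assemble_dpi_dataset(
    positives: set,
    scores: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
    compounds: Sequence[CompoundRecord],
    protein_table: KmerEmbeddingTable,
    compound_table: KmerEmbeddingTable,
    max_compounds: int = 50000,
) -> DPIDataset:
    """Build the labeled DPI training set (positive list + quartile negatives)."""
    if not positives:
        raise ArgumentError("positives must be non-empty")
    if scores.empty:
        raise ArgumentError("scores must be non-empty")
    negatives = quartile_negative_pairs(scores, positives, max_compounds)
    if negatives.empty:
        raise DataError("lower-quartile rule yielded zero negative pairs")

    prot_by_id = {p.id: p for p in proteins}
    comp_by_id = {c.id: c for c in compounds}
    prot_vec_cache, comp_vec_cache = {}, {}

    def pvec(pid):
        if pid not in prot_vec_cache:
            prot_vec_cache[pid] = embed_protein(prot_by_id[pid], protein_table)
        return prot_vec_cache[pid]

    def cvec(cid):
        if cid not in comp_vec_cache:
            comp_vec_cache[cid] = embed_compound(comp_by_id[cid].smiles, compound_table)
        return comp_vec_cache[cid]

    rows, feats = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, cid in sorted(positives):
            if pid not in prot_by_id or cid not in comp_by_id:
                raise DataError(f"positive pair ({pid}, {cid}) lacks a record")
            rows.append((pid, cid, 1, "positive_list"))
            feats.append(np.concatenate([pvec(pid), cvec(cid)]))
        for _, rec in negatives.sort_values(["protein_id", "compound_id"]).iterrows():
            pid, cid = rec["protein_id"], rec["compound_id"]
            if pid not in prot_by_id or cid not in comp_by_id:
                raise DataError(f"scored pair ({pid}, {cid}) lacks a record")
            rows.append((pid, cid, 0, "quartile_negative"))
            feats.append(np.concatenate([pvec(pid), cvec(cid)]))
    frame = pd.DataFrame(rows, columns=["protein_id", "compound_id", "label", "provenance"])
    return DPIDataset(
        frame=frame,
        features=np.vstack(feats),
        vector_dim=protein_table.dimension,
    )


def train_dpi_model(
    dataset: DPIDataset,
    arch: Optional[dict] = None,
    folds: int = 5,
    seed: int = 0,
):
    """Cross-validated DPI classifier on concatenated embeddings."""
    if dataset.features.shape[1] != 2 * dataset.vector_dim:
        raise DataError(
            f"feature dimension {dataset.features.shape[1]} != 2 x {dataset.vector_dim}"
        )
    X = pd.DataFrame(dataset.features, index=dataset.frame.index)
    y = pd.Series(dataset.frame["label"].to_numpy(), index=dataset.frame.index)
    return cross_validated_classifier(X, y, folds=folds, arch=arch, seed=seed)


@dataclass
class CandidateHit:
    protein_id: str
    compound_id: str
    probability: float


def screen_library(
    model,
    proteins: Sequence[ProteinRecord],
    library: Sequence[CompoundRecord],
    threshold: float,
    protein_table: KmerEmbeddingTable,
    compound_table: KmerEmbeddingTable,
) -> list:
    """Score every (protein, compound) pair; return hits above ``threshold``.

    Hits are sorted by probability descending, ties by (protein id,
    compound id).  Compounds that cannot be embedded (unparseable SMILES)
    are skipped and counted in a warning.
    """
    if not 0 <= threshold <= 1:
        raise ArgumentError("threshold must lie in [0, 1]")
    comp_vecs, skipped = {}, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in library:
            try:
                comp_vecs[rec.id] = embed_compound(rec.smiles, compound_table)
            except SmilesParseError:
                skipped += 1
        prot_vecs = {p.id: embed_protein(p, protein_table) for p in proteins}
    if skipped:
        warnings.warn(f"{skipped} compounds could not be embedded; skipped")
    pairs, feats = [], []
    for p in proteins:
        for cid, cv in comp_vecs.items():
            pairs.append((p.id, cid))
            feats.append(np.concatenate([prot_vecs[p.id], cv]))
    if not pairs:
        return []
    probs = model.predict_proba(np.vstack(feats))[:, 1]
    hits = [
        CandidateHit(protein_id=p, compound_id=c, probability=float(pr))
        for (p, c), pr in zip(pairs, probs)
        if pr > threshold
    ]
    hits.sort(key=lambda h: (-h.probability, h.protein_id, h.compound_id))
    return hits


def tally_hits_per_gene(hits: Sequence[CandidateHit]) -> pd.DataFrame:
    """Per-gene inhibitor counts, sorted descending (ties by gene id)."""
    counts = {}
    for h in hits:
        counts[h.protein_id] = counts.get(h.protein_id, 0) + 1
    items = sorted(counts.items(), key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(items, columns=["gene", "n_inhibitors"])
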