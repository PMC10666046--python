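"""Shared domain containers.

Expression data travels as a pandas DataFrame (genes as rows, samples as
columns, non-negative values) wrapped in :class:`ExpressionMatrix` so the
normalization state travels with it.  Clinical tables, score tables and
sensitivity records are plain DataFrames with documented column conventions;
the dataclasses below bundle them with planted ground truth where a synthetic
generator produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``values.index`` are unique gene ids, ``values.columns`` unique sample
    ids.  ``normalized_to`` records the housekeeping gene used for
    normalization, or ``None`` for raw values.
    """

    values: pd.DataFrame
    normalized_to: Optional[str] = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if self.values.columns.has_duplicates:
            raise ValueError("sample identifiers must be unique")


# Clinical table column conventions (CSV round-trips with these names).
CLINICAL_COLUMNS = ["patient_id", "os_time", "os_event", "pfi_time", "pfi_event"]


@dataclass
class SyntheticCohort:
    """Expression + clinical outcomes with planted prognostic genes."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # columns per CLINICAL_COLUMNS
    planted_prognostic_genes: frozenset
    effect_size: float


@dataclass
class SyntheticTissuePanel:
    """Expression + tumor/normal labels with planted discriminative genes."""

    expression: ExpressionMatrix
    labels: pd.Series  # sample id -> "tumor" | "normal"
    planted_discriminative_genes: frozenset


@dataclass
class ProteinRecord:
    id: str
    sequence: str


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    vector: Optional[list] = None


@dataclass
class SyntheticInteractionWorld:
    """Proteins, compounds, an interaction-score table and hidden positives.

    ``score_table`` columns: compound_id, protein_id, score (in [0, 1]).
    ``positive_pairs`` holds (protein_id, compound_id) tuples labelled
    positive by the hidden rule; ``latents`` maps entity id -> latent vector
    so tests can evaluate the rule directly.
    """

    proteins: list
    compounds: list
    score_table: pd.DataFrame
    positive_pairs: frozenset
    planted_rule: str
    latents: dict = field(default_factory=dict)
    rule_cutoff: float = 0.0


@dataclass
class CellLineProfile:
    id: str
    expression: pd.Series  # gene id -> value


@dataclass
class SyntheticSensitivityPanel:
    """Cell lines + binary IC50-success records with planted driver genes."""

    cell_lines: list
    sensitivity: pd.DataFrame  # columns: line_id, compound_id, success
    planted_gene_set: frozenset
    compound_latents: dict = field(default_factory=dict)


@dataclass
class LiteratureCorpus:
    """Document id -> text, plus planted ground truth for synthetic corpora."""

    documents: dict
    planted_pairs: list = field(default_factory=list)  # (doc_id, gene, inhibitor)
    planted_placements: dict = field(default_factory=dict)  # doc_id -> entity set


@dataclass
class CVReport:
    """Per-fold out-of-fold ROC-AUCs of a cross-validated classifier."""

    fold_aucs: list
    fold_assignments: pd.Series  # sample id -> fold index

    @property
    def mean_auc(self) -> float:
        return float(sum(self.fold_aucs) / len(self.fold_aucs))

    @property
    def n_folds(self) -> int:
        return len(self.fold_aucs)


@dataclass
class GeneRanking:
    """(gene, importance) pairs sorted non-increasing by importance."""

    entries: list  # list of (gene_id, importance >= 0)
    method: str

    def __post_init__(self) -> None:
        imps = [i for _, i in self.entries]
        if any(b > a + 1e-12 for a, b in zip(imps, imps[1:])):
            raise ValueError("ranking must be sorted non-increasing")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids in a ranking must be unique")

    @property
    def genes(self) -> list:
        return [g for g, _ in self.entries]

    def importance(self, gene: str) -> float:
        for g, i in self.entries:
            if g == gene:
                return i
        raise KeyError(gene)

    def top(self, k: int) -> list:
        return self.genes[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "importance": [i for _, i in self.entries],
                "rank": range(1, len(self.entries) + 1),
                "method": self.method,
            }
        )


@dataclass
class OutcomeLabels:
    """Binary above-median outcome labels for one endpoint (OS or PFI)."""

    labels: pd.Series  # patient id -> {0, 1}
    endpoint: str
    median_used: float


@dataclass
class PredictionMatrix:
    """Molecules x cell lines matrix of IC50-success probabilities."""

    probabilities: pd.DataFrame  # index: molecule ids, columns: line ids

    def __post_init__(self) -> None:
        import numpy as np

        vals = self.probabilities.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.probabilities.index.has_duplicates or self.probabilities.columns.has_duplicates:
            raise ValueError("molecule and line ids must be unique")
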