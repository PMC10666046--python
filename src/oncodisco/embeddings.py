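"""Token embeddings for proteins and compounds.

Proteins are read as amino-acid 3-mers (k shifted non-overlapping readings
per sequence, the ProtVec reading scheme); compounds as Morgan circular
substructure identifiers in canonical atom order (the mol2vec sentence).
Tokens are embedded by factorizing the windowed positive-PMI co-occurrence
matrix with a truncated SVD — the count-based closed form of skip-gram with
negative sampling — and an entity's vector is the sum of its token vectors.

Tables round-trip losslessly through a TSV format whose header records the
token kind, dimension, k/radius and training seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import sparse
from sklearn.decomposition import TruncatedSVD

from .errors import ArgumentError, EmbeddingLookupError, SmilesParseError
from .types import ProteinRecord


@dataclass
class KmerEmbeddingTable:
    """token -> d-dimensional vector, all vectors the same dimension."""

    kind: str  # "aa_3mer" | "substructure_id"
    dimension: int
    k_or_radius: int
    seed: int
    vectors: dict = field(default_factory=dict)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[token]
        except KeyError:
            raise EmbeddingLookupError(
                f"token {token!r} absent from {self.kind} embedding table"
            ) from None

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#kind={self.kind}\td={self.dimension}\t"
                f"k_or_radius={self.k_or_radius}\tseed={self.seed}\n"
            )
            for token in sorted(self.vectors):
                vals = "\t".join(repr(float(v)) for v in self.vectors[token])
                fh.write(f"{token}\t{vals}\n")

    @classmethod
    def load(cls, path) -> "KmerEmbeddingTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(part.split("=", 1) for part in header.split("\t"))
            vectors = {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
        return cls(
            kind=meta["kind"],
            dimension=int(meta["d"]),
            k_or_radius=int(meta["k_or_radius"]),
            seed=int(meta["seed"]),
            vectors=vectors,
        )


# ---------------------------------------------------------------------------
# Protein k-mer sentences
# ---------------------------------------------------------------------------

def protein_corpus(sequences: Sequence[ProteinRecord], k: int = 3) -> List[List[str]]:
    """Sentences of consecutive k-mers: k shifted non-overlapping readings.

    For each sequence and each offset 0..k-1, residues are grouped into
    consecutive k-mers starting at that offset; an incomplete tail is
    dropped.  Sequences shorter than k are skipped with a warning.
    """
    if k < 1:
        raise ArgumentError("k must be >= 1")
    corpus: List[List[str]] = []
    for rec in sequences:
        seq = rec.sequence if isinstance(rec, ProteinRecord) else str(rec)
        if len(seq) < k:
            warnings.warn(f"sequence shorter than k={k}; skipped")
            continue
        for offset in range(k):
            sentence = [
                seq[i : i + k]
                for i in range(offset, len(seq) - k + 1, k)
            ]
            if sentence:
                corpus.append(sentence)
    return corpus


# ---------------------------------------------------------------------------
# Embedding training (PPMI + truncated SVD)
# ---------------------------------------------------------------------------

def train_token_embedding(
    corpus: Iterable[List[str]],
    d: int = 100,
    window: int = 5,
    epochs: Optional[int] = None,
    seed: int = 0,
    kind: str = "aa_3mer",
    k_or_radius: int = 3,
) -> KmerEmbeddingTable:
    """Learn d-dimensional token vectors from windowed co-occurrence.

    Positive pointwise mutual information of within-window token pairs is
    factorized with a truncated SVD; vectors are U * sqrt(S).  This is the
    closed-form count-based formulation of skip-gram embedding, so ``epochs``
    is accepted for interface compatibility but has no effect.  Every token
    that occurs in the corpus receives a vector; determinism follows from
    the fixed seed of the randomized SVD.
    """
    corpus = [list(sent) for sent in corpus]
    if not corpus or all(not s for s in corpus):
        raise ArgumentError("corpus must be non-empty")
    if d < 2:
        raise ArgumentError("embedding dimension must be >= 2")
    vocab = sorted({tok for sent in corpus for tok in sent})
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)

    rows, cols = [], []
    for sent in corpus:
        ids = [index[t] for t in sent]
        for i, ti in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    rows.append(ti)
                    cols.append(ids[j])
    counts = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(V, V)
    ).tocsr()

    total = counts.sum()
    row_sums = np.asarray(counts.sum(axis=1)).ravel()
    col_sums = np.asarray(counts.sum(axis=0)).ravel()
    coo = counts.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data * total / (row_sums[coo.row] * col_sums[coo.col]))
    keep = pmi > 0
    ppmi = sparse.csr_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=(V, V)
    )

    d_eff = min(d, V - 1) if V > 1 else 1
    if d_eff < 1 or ppmi.nnz == 0:
        mat = np.zeros((V, d))
    else:
        svd = TruncatedSVD(n_components=d_eff, random_state=seed, n_iter=7)
        u = svd.fit_transform(ppmi)  # = U * S
        mat = u / np.sqrt(np.maximum(svd.singular_values_, 1e-12))  # U
        mat = mat * np.sqrt(svd.singular_values_)  # U * sqrt(S)
        if d_eff < d:
            mat = np.hstack([mat, np.zeros((V, d - d_eff))])
    vectors = {tok: mat[i].copy() for tok, i in index.items()}
    return KmerEmbeddingTable(
        kind=kind, dimension=d, k_or_radius=k_or_radius, seed=seed, vectors=vectors
    )


# ---------------------------------------------------------------------------
# Sum embeddings
# ---------------------------------------------------------------------------

def _sum_tokens(
    tokens: Sequence[str], table: KmerEmbeddingTable, oov_rule: str
) -> np.ndarray:
    out = np.zeros(table.dimension)
    n_oov = 0
    for tok in tokens:
        if tok in table:
            out += table.vectors[tok]
        elif oov_rule == "zero":
            n_oov += 1
        else:
            raise EmbeddingLookupError(f"out-of-vocabulary token {tok!r}")
    if n_oov:
        warnings.warn(f"{n_oov} out-of-vocabulary tokens contributed zero")
    return out


def embed_protein(
    sequence, table: KmerEmbeddingTable, oov_rule: str = "zero"
) -> np.ndarray:
    """Vector sum of the k-mer tokens of all shifted readings of a sequence.

    Out-of-vocabulary tokens contribute zero and are counted in a warning
    (``oov_rule="zero"``, default) or raise (``oov_rule="error"``).
    """
    if table.kind != "aa_3mer":
        raise ArgumentError(f"expected an aa_3mer table, got {table.kind!r}")
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else str(sequence)
    k = table.k_or_radius
    if len(seq) < k:
        raise ArgumentError(f"sequence shorter than k={k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-record corpus: no skip warnings
        sentences = protein_corpus([ProteinRecord(id="_", sequence=seq)], k=k)
    tokens = [tok for sent in sentences for tok in sent]
    return _sum_tokens(tokens, table, oov_rule)


def compound_sentence(smiles: str, radius: int = 1) -> List[str]:
    """Morgan circular-substructure identifiers per atom and radius.

    For each atom (in canonical order) and each radius 0..``radius``, the
    identifier of the circular environment rooted there, when that
    environment exists (e.g. an isolated atom has no radius-1 environment).
    Identifiers are RDKit's invariant-hashed Morgan bit ids, stable across
    runs and platforms.
    """
    if radius < 0:
        raise ArgumentError("radius must be >= 0")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radius, 1))
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    env = {}  # (atom_idx, radius) -> bit id
    for bit, entries in ao.GetBitInfoMap().items():
        for atom_idx, rad in entries:
            env[(atom_idx, rad)] = bit
    order = np.argsort(list(Chem.CanonicalRankAtoms(mol, breakTies=True)))
    sentence = []
    for atom_idx in order:
        for rad in range(radius + 1):
            bit = env.get((int(atom_idx), rad))
            if bit is not None:
                sentence.append(f"sub_{bit}")
    return sentence


def embed_compound(
    smiles: str, table: KmerEmbeddingTable, oov_rule: str = "zero", radius: Optional[int] = None
) -> np.ndarray:
    """Vector sum of a compound's substructure tokens (same OOV contract as proteins)."""
    if table.kind != "substructure_id":
        raise ArgumentError(f"expected a substructure_id table, got {table.kind!r}")
    tokens = compound_sentence(
        smiles, radius=table.k_or_radius if radius is None else radius
    )
    return _sum_tokens(tokens, table, oov_rule)


def compound_corpus(compounds, radius: int = 1) -> List[List[str]]:
    """One substructure sentence per compound (skipping unparseable SMILES with a warning)."""
    corpus = []
    for rec in compounds:
        smiles = rec.smiles if hasattr(rec, "smiles") else str(rec)
        try:
            corpus.append(compound_sentence(smiles, radius=radius))
        except SmilesParseError:
            warnings.warn(f"skipping unparseable SMILES {smiles!r}")
    return corpus
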