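"""Readers and writers for the pipeline's plain-text interchange formats.

Expression: TSV, genes as rows, header = sample ids.  Clinical: CSV with the
standard column names.  Proteins: FASTA.  Compounds: one SMILES per line
with a tab-separated id.  Scores: TSV triples (compound_id, protein_id,
score).  Corpora: JSONL with {"id", "text"} objects.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CompoundRecord, ExpressionMatrix, LiteratureCorpus, ProteinRecord


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix(frame)


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_smiles(compounds: Sequence[CompoundRecord], path) -> None:
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles}\t{c.id}\n")


def read_smiles(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            smiles, _, cid = line.partition("\t")
            out.append(CompoundRecord(id=cid or f"CMPD{len(out) + 1:05d}", smiles=smiles))
    return out


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores[["compound_id", "protein_id", "score"]].to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_corpus_jsonl(corpus: LiteratureCorpus, path) -> None:
    with open(path, "w") as fh:
        for doc_id, text in corpus.documents.items():
            fh.write(json.dumps({"id": doc_id, "text": text}) + "\n")


def read_corpus_jsonl(path) -> LiteratureCorpus:
    documents = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                documents[obj["id"]] = obj["text"]
    return LiteratureCorpus(documents=documents)
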