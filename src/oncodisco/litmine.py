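"""Stage 3 — literature mining with a deterministic gazetteer/pattern NER.

Builds gene x keyword article-count tables (document-level co-occurrence,
matching PubMed-query semantics) and extracts gene-inhibitor pairs from
abstracts by same-sentence matching: genes against a lexicon, inhibitors
against a lexicon and/or surface patterns (the "-inib" suffix family of
kinase-inhibitor INN names, and letter-digit development codes such as
sb203580).  Every operation is deterministic; an adapter can swap in a
learned NER behind the same contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ArgumentError
from .types import LiteratureCorpus

#: Query keywords of the standard per-gene report (one column each, plus a
#: total-mentions column summing them).
DEFAULT_KEYWORDS = ["target", "cancer", "lung cancer", "phase", "drug", "approval", "FDA"]

_TOKEN_RE = re.compile(r"[A-Za-z0-9\-]+")
_SENTENCE_RE = re.compile(r"[^.!?]+[.!?]?")
#: Development-code pattern: short letter prefix + >= 3 digits (+ optional tail).
DEFAULT_CODE_RE = re.compile(r"^[a-z]{1,4}\d{3,}[a-z0-9]*$")
#: "-nib" is the USAN/INN stem of small-molecule kinase inhibitors and covers
#: the -tinib / -anib / -fenib substems (gefitinib, vemurafenib, ...).
DEFAULT_SUFFIXES = ("nib",)


def _documents(corpus) -> dict:
    if isinstance(corpus, LiteratureCorpus):
        return corpus.documents
    return dict(corpus)


def _tokens(text: str) -> list:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def _contains_phrase(tokens: list, phrase: str) -> bool:
    """Case-insensitive whole-token match; multi-word phrases must appear as
    consecutive tokens."""
    want = [w.lower() for w in _TOKEN_RE.findall(phrase)]
    if not want:
        return False
    if len(want) == 1:
        return want[0] in tokens
    n = len(want)
    return any(tokens[i : i + n] == want for i in range(len(tokens) - n + 1))


def count_cooccurrence(
    corpus,
    genes: Sequence[str],
    keywords: Optional[Sequence[str]] = None,
    match_rule: str = "whole_token",
) -> pd.DataFrame:
    """Gene x keyword table of document-level co-occurrence counts.

    Cell (g, w) = number of documents containing both the gene and the
    keyword as whole tokens (phrases as consecutive tokens), case
    insensitive.  A ``total_mentions`` column sums the keyword columns.
    """
    if match_rule != "whole_token":
        raise ArgumentError(f"unknown match rule {match_rule!r}")
    if not genes:
        raise ArgumentError("gene list must be non-empty")
    keywords = list(DEFAULT_KEYWORDS if keywords is None else keywords)
    if not keywords:
        raise ArgumentError("keyword list must be non-empty")
    docs = _documents(corpus)
    counts = pd.DataFrame(0, index=list(genes), columns=keywords)
    for text in docs.values():
        toks = _tokens(text)
        present_genes = [g for g in genes if _contains_phrase(toks, g)]
        if not present_genes:
            continue
        present_kw = [w for w in keywords if _contains_phrase(toks, w)]
        for g in present_genes:
            for w in present_kw:
                counts.loc[g, w] += 1
    counts["total_mentions"] = counts[keywords].sum(axis=1)
    counts.index.name = "gene"
    return counts


@dataclass
class GeneInhibitorPair:
    """A same-sentence gene/inhibitor mention with its evidence spans."""

    doc_id: str
    gene: str
    gene_span: tuple
    inhibitor: str
    inhibitor_span: tuple
    rule: str


def extract_pairs(
    corpus,
    gene_lexicon: Sequence[str],
    inhibitor_patterns: Optional[dict] = None,
) -> list:
    """Deterministic same-sentence gene-inhibitor pair extraction.

    ``inhibitor_patterns`` keys: ``lexicon`` (known inhibitor names),
    ``suffixes`` (token endings, default ``("inib",)``), ``code_pattern``
    (regex for development codes).  Gene-lexicon tokens are never emitted as
    inhibitors.  Each (document, gene, inhibitor) pair is reported once,
    with the spans of its first same-sentence evidence.
    """
    if not gene_lexicon:
        raise ArgumentError("gene lexicon must be non-empty")
    patterns = inhibitor_patterns or {}
    inh_lexicon = {w.lower() for w in patterns.get("lexicon", [])}
    suffixes = tuple(patterns.get("suffixes", DEFAULT_SUFFIXES))
    code_re = patterns.get("code_pattern", DEFAULT_CODE_RE)
    if isinstance(code_re, str):
        code_re = re.compile(code_re)
    genes = {g.lower(): g for g in gene_lexicon}

    def inhibitor_rule(token: str) -> Optional[str]:
        if token in genes:
            return None
        if token in inh_lexicon:
            return "lexicon"
        if any(token.endswith(s) for s in suffixes) and len(token) > 4:
            return "suffix"
        if code_re.match(token):
            return "code"
        return None

    pairs, seen = [], set()
    for doc_id, text in _documents(corpus).items():
        offset = 0
        for sent_match in _SENTENCE_RE.finditer(text):
            sentence = sent_match.group()
            base = sent_match.start()
            gene_hits, inh_hits = [], []
            for m in _TOKEN_RE.finditer(sentence):
                tok = m.group().lower()
                span = (base + m.start(), base + m.end())
                if tok in genes:
                    gene_hits.append((genes[tok], span))
                else:
                    rule = inhibitor_rule(tok)
                    if rule:
                        inh_hits.append((m.group(), span, rule))
            for gene, gspan in gene_hits:
                for inh, ispan, rule in inh_hits:
                    key = (doc_id, gene, inh.lower())
                    if key in seen:
                        continue
                    seen.add(key)
                    pairs.append(
                        GeneInhibitorPair(
                            doc_id=doc_id,
                            gene=gene,
                            gene_span=gspan,
                            inhibitor=inh,
                            inhibitor_span=ispan,
                            rule=rule,
                        )
                    )
    return pairs


def attach_inhibitor_column(
    table: pd.DataFrame, pairs: Sequence[GeneInhibitorPair]
) -> pd.DataFrame:
    """Append a per-gene alphabetized, deduplicated inhibitor-list column."""
    by_gene = {}
    for p in pairs:
        by_gene.setdefault(p.gene, set()).add(p.inhibitor.lower())
    out = table.copy()
    out["inhibitors"] = [
        "; ".join(sorted(by_gene.get(g, set()))) for g in out.index
    ]
    return out
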