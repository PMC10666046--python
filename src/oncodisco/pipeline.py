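"""End-to-end orchestration of the five pipeline stages on synthetic data.

Stage order: prognostic targets → tumor/normal filter → literature mining →
drug-protein interaction screening → preclinical IC50 emulation and
selectivity filtering.  One global seed deterministically derives per-stage
seeds (stable hash of stage name + seed), each stage's outputs are written
to the run directory before the next stage starts, and the run report
records per-stage metrics plus SHA-256 digests of every output file, so a
rerun with identical config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as odio
from .cohort_prognosis import (
    augment_with_gan,
    binarize_outcome,
    merge_gene_lists,
    normalize_expression,
    rank_features_lasso,
    train_outcome_classifier,
)
from .config import PipelineConfig
from .dpi import (
    assemble_dpi_dataset,
    positive_overlap_summary,
    screen_library,
    tally_hits_per_gene,
    train_dpi_model,
)
from .embeddings import (
    compound_corpus,
    protein_corpus,
    train_token_embedding,
)
from .errors import DataError
from .litmine import attach_inhibitor_column, count_cooccurrence, extract_pairs
from .models import cross_validated_classifier
from .preclinical import (
    assemble_cell_dataset,
    decompose_molecule,
    filter_by_target_lines,
    predict_matrix,
    selectivity_filter,
    train_ic50_model,
)
from .synthetic_data import (
    REFERENCE_GENE,
    generate_cohort,
    generate_compounds,
    generate_corpus,
    generate_interaction_world,
    generate_proteins,
    generate_sensitivity_panel,
    generate_tissue_panel,
)
from .tumor_normal import (
    intersect_targets,
    rank_tissue_genes,
    select_discriminative_genes,
    train_tissue_classifier,
)
from .types import CompoundRecord, ProteinRecord


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of stage name + global seed, below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def designate_target_lines(predictions: pd.DataFrame, n: int = 2) -> list:
    """Choose reference cell lines from the model's training-compound predictions.

    The first line is the one whose predicted probabilities spread the most
    across compounds (the model discriminates on it); subsequent lines are
    those whose prediction profiles correlate best with the first, i.e.
    lines expected to respond concordantly — the in-silico analogue of
    choosing a pair of commonly used, similarly behaving reference lines.
    """
    spread = predictions.std(axis=0)
    first = spread.sort_values(ascending=False, kind="stable").index[0]
    if n == 1:
        return [first]
    corr = predictions.corrwith(predictions[first])
    rest = corr.drop(index=first).sort_values(ascending=False, kind="stable")
    return [first] + list(rest.index[: n - 1])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all five stages on synthetic data; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.model_dump(),
        "seed": config.seed,
        "stages": {},
        "digests": {},
        "warnings": [],
    }
    files: dict = {}

    def write(name, writer, *args):
        path = out / name
        writer(*args, path)
        files[name] = path

    t_all = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _stage_targets(config, report, write)
        _stage_filter(config, report, write)
        if config.litmine.enabled:
            _stage_litmine(config, report, write)
        else:
            report["stages"]["litmine"] = {"skipped": True}
        _stage_dpi(config, report, write)
        _stage_preclinical(config, report, write)

    report["elapsed_s"] = round(time.time() - t_all, 2)
    for name, path in files.items():
        report["digests"][name] = _sha256(path)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


# ---------------------------------------------------------------------------
# Stage 1: prognostic targets
# ---------------------------------------------------------------------------

def _stage_targets(config: PipelineConfig, report, write) -> None:
    t0 = time.time()
    cfg = config.cohort
    seed = stage_seed(config.seed, "targets")
    cohort = generate_cohort(
        cfg.n_patients, cfg.n_genes, cfg.n_prognostic, cfg.effect_size, seed
    )
    write("expression.tsv", odio.write_expression_tsv, cohort.expression)
    write("clinical.csv", odio.write_clinical_csv, cohort.clinical)
    norm = normalize_expression(cohort.expression, REFERENCE_GENE)

    rankings = {}
    metrics = {"endpoints": {}}
    for endpoint in cfg.endpoints:
        labels = binarize_outcome(cohort.clinical, endpoint)
        _, cv = train_outcome_classifier(
            norm, labels, folds=cfg.folds, seed=seed
        )
        table = np.log1p(norm.values.T.loc[labels.labels.index])
        table["label"] = labels.labels.values
        aug = augment_with_gan(table, cfg.augment, seed=seed)
        drop = [c for c in ("label", "synthetic") if c in aug.columns]
        Xa, ya = aug.drop(columns=drop), aug["label"]
        _, cv_aug = cross_validated_classifier(Xa, ya, folds=cfg.folds, seed=seed)
        ranking = rank_features_lasso(Xa, ya, folds=cfg.folds, seed=seed)
        rankings[endpoint] = ranking
        metrics["endpoints"][endpoint] = {
            "median_days": labels.median_used,
            "cv_auc": cv.mean_auc,
            "cv_auc_augmented": cv_aug.mean_auc,
            "fold_aucs": cv.fold_aucs,
            "n_ranked": len(ranking.entries),
        }
    os_rank = rankings.get("OS", rankings[cfg.endpoints[0]])
    pfi_rank = rankings.get("PFI", rankings[cfg.endpoints[-1]])
    prognostic = merge_gene_lists(os_rank, pfi_rank, cfg.top_k)
    frames = [r.to_frame().assign(endpoint=e) for e, r in rankings.items()]
    write(
        "rankings.csv",
        lambda df, p: df.to_csv(p, index=False),
        pd.concat(frames, ignore_index=True),
    )
    write(
        "prognostic_genes.csv",
        lambda df, p: df.to_csv(p, index=False),
        pd.DataFrame({"gene": prognostic, "rank": range(1, len(prognostic) + 1)}),
    )
    metrics.update(
        {
            "n_prognostic_candidates": len(prognostic),
            "planted_genes": sorted(cohort.planted_prognostic_genes),
            "planted_recovered": len(
                set(prognostic) & cohort.planted_prognostic_genes
            ),
            "elapsed_s": round(time.time() - t0, 2),
        }
    )
    report["stages"]["targets"] = metrics
    report["_prognostic"] = prognostic
    report["_gene_ids"] = [g for g in cohort.expression.genes if g != REFERENCE_GENE]
    report["_cohort_planted"] = sorted(cohort.planted_prognostic_genes)


# ---------------------------------------------------------------------------
# Stage 2: tumor/normal filter
# ---------------------------------------------------------------------------

def _stage_filter(config: PipelineConfig, report, write) -> None:
    t0 = time.time()
    cfg = config.tissue
    seed = stage_seed(config.seed, "filter")
    gene_ids = report["_gene_ids"]
    rng = np.random.default_rng(seed)
    # plant the cohort's prognostic genes plus extra tumour markers so the
    # two stages share a recoverable joint signal
    planted = list(report["_cohort_planted"])
    others = [g for g in gene_ids if g not in set(planted)]
    extra = cfg.n_discriminative - len(planted)
    if extra > 0:
        planted += list(rng.choice(others, size=extra, replace=False))
    planted = sorted(planted[: cfg.n_discriminative])
    panel = generate_tissue_panel(
        cfg.n_tumor,
        cfg.n_normal,
        len(gene_ids),
        len(planted),
        cfg.shift,
        seed,
        gene_ids=gene_ids,
        discriminative_genes=planted,
    )
    _, cv = train_tissue_classifier(panel.expression, panel.labels, folds=cfg.folds, seed=seed)
    ranking = rank_tissue_genes(
        panel.expression, panel.labels, folds=cfg.folds, seed=seed, n_repeats=2
    )
    selection = select_discriminative_genes(ranking, {"top_k": cfg.select_top_k})
    targets = intersect_targets(report["_prognostic"], selection)
    if not targets:
        report["warnings"].append(
            "tumor/normal filter removed every prognostic gene; "
            "falling back to the top 5 prognostic candidates"
        )
        targets = report["_prognostic"][:5]
    write(
        "targets.csv",
        lambda df, p: df.to_csv(p, index=False),
        pd.DataFrame(
            {
                "gene": targets,
                "stage1_rank": [report["_prognostic"].index(g) + 1 for g in targets],
                "stage2_importance": [
                    dict(ranking.entries).get(g, 0.0) for g in targets
                ],
            }
        ),
    )
    jointly_planted = set(report["_cohort_planted"]) & panel.planted_discriminative_genes
    report["stages"]["filter"] = {
        "cv_auc": cv.mean_auc,
        "n_selected": len(selection.genes),
        "n_targets": len(targets),
        "jointly_planted": sorted(jointly_planted),
        "jointly_planted_recovered": len(set(targets) & jointly_planted),
        "elapsed_s": round(time.time() - t0, 2),
    }
    report["_targets"] = targets
    report["_panel"] = panel  # reused by preclinical; stripped before JSON


# ---------------------------------------------------------------------------
# Stage 3: literature mining
# ---------------------------------------------------------------------------

def _stage_litmine(config: PipelineConfig, report, write) -> None:
    t0 = time.time()
    cfg = config.litmine
    seed = stage_seed(config.seed, "litmine")
    targets = report["_targets"]
    rng = np.random.default_rng(seed)
    inhibitors = [f"cp{int(x):06d}" for x in rng.integers(100000, 999999, size=8)]
    inhibitors += [f"vq{i}inib" for i in range(1, 5)]
    from .litmine import DEFAULT_KEYWORDS

    corpus = generate_corpus(targets, inhibitors, DEFAULT_KEYWORDS, cfg.n_docs, seed)
    write("corpus.jsonl", odio.write_corpus_jsonl, corpus)
    table = count_cooccurrence(corpus, targets)
    pairs = extract_pairs(corpus, targets)
    table = attach_inhibitor_column(table, pairs)
    write("litmine_table.csv", lambda df, p: df.to_csv(p), table)
    extracted = {(p.doc_id, p.gene, p.inhibitor.lower()) for p in pairs}
    truth = {(d, g, i.lower()) for d, g, i in corpus.planted_pairs}
    tp = len(extracted & truth)
    report["stages"]["litmine"] = {
        "n_docs": cfg.n_docs,
        "n_pairs": len(pairs),
        "pair_precision": tp / len(extracted) if extracted else 1.0,
        "pair_recall": tp / len(truth) if truth else 1.0,
        "elapsed_s": round(time.time() - t0, 2),
    }


# ---------------------------------------------------------------------------
# Stage 4: drug-protein interactions
# ---------------------------------------------------------------------------

def _stage_dpi(config: PipelineConfig, report, write) -> None:
    t0 = time.time()
    cfg = config.dpi
    seed = stage_seed(config.seed, "dpi")
    targets = report["_targets"]
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(2**31, size=5)]

    target_proteins = generate_proteins(
        len(targets), (80, 240), seeds[0], composition_alpha=0.5, id_prefix="TGT"
    )
    target_proteins = [
        ProteinRecord(id=gene, sequence=p.sequence)
        for gene, p in zip(targets, target_proteins)
    ]
    background = generate_proteins(
        cfg.n_background_proteins, (80, 240), seeds[1], composition_alpha=0.5
    )
    proteins = target_proteins + background
    compounds = generate_compounds(cfg.n_train_compounds, seeds[2])
    world = generate_interaction_world(proteins, compounds, cfg.pos_fraction, seeds[3])
    write("proteins.fasta", odio.write_fasta, proteins)
    write("compound_library.smi", odio.write_smiles, compounds)
    write("interaction_scores.tsv", odio.write_scores_tsv, world.score_table)

    overlap = positive_overlap_summary(world.score_table, world.positive_pairs)
    ptable = train_token_embedding(
        protein_corpus(proteins), d=cfg.embedding_dim, seed=seeds[4],
        kind="aa_3mer", k_or_radius=3,
    )
    ctable = train_token_embedding(
        compound_corpus(compounds), d=cfg.embedding_dim, seed=seeds[4] + 1,
        kind="substructure_id", k_or_radius=1,
    )
    write("protein_embeddings.tsv", lambda t, p: t.save(p), ptable)
    write("compound_embeddings.tsv", lambda t, p: t.save(p), ctable)
    dataset = assemble_dpi_dataset(
        world.positive_pairs, world.score_table, proteins, compounds, ptable, ctable
    )
    model, cv = train_dpi_model(dataset, folds=cfg.folds, seed=seed)
    hits = screen_library(
        model, target_proteins, compounds, cfg.screen_threshold, ptable, ctable
    )
    tally = tally_hits_per_gene(hits)
    write(
        "dpi_hits.csv",
        lambda df, p: df.to_csv(p, index=False),
        pd.DataFrame(
            [(h.protein_id, h.compound_id, h.probability) for h in hits],
            columns=["gene", "compound", "probability"],
        ),
    )
    write("dpi_tally.csv", lambda df, p: df.to_csv(p, index=False), tally)

    hit_pairs = {(h.protein_id, h.compound_id) for h in hits}
    true_rate = (
        np.mean([pair in world.positive_pairs for pair in hit_pairs])
        if hit_pairs
        else 0.0
    )
    report["stages"]["dpi"] = {
        "n_pairs": len(dataset.frame),
        "n_positive": int((dataset.frame.label == 1).sum()),
        "n_negative": int((dataset.frame.label == 0).sum()),
        "cv_auc": cv.mean_auc,
        "score_overlap": overlap["overlap"],
        "n_hits": len(hits),
        "hit_true_rate": float(true_rate),
        "elapsed_s": round(time.time() - t0, 2),
    }
    comp_by_id = {c.id: c for c in compounds}
    report["_hit_compounds"] = sorted({h.compound_id for h in hits})
    report["_compounds"] = compounds
    report["_comp_by_id"] = comp_by_id
    report["_ctable"] = ctable
    report["_world"] = world


# ---------------------------------------------------------------------------
# Stage 5: preclinical emulation
# ---------------------------------------------------------------------------

def _stage_preclinical(config: PipelineConfig, report, write) -> None:
    t0 = time.time()
    cfg = config.preclinical
    seed = stage_seed(config.seed, "preclinical")
    panel = report.pop("_panel")
    compounds = report.pop("_compounds")
    ctable = report.pop("_ctable")
    comp_by_id = report.pop("_comp_by_id")
    world = report.pop("_world")
    hit_ids = report.pop("_hit_compounds")

    assay_compounds = compounds[: cfg.n_assay_compounds]
    sens = generate_sensitivity_panel(
        panel,
        assay_compounds,
        cfg.n_lines,
        seed,
        n_driver_genes=cfg.n_driver_genes,
        steepness=cfg.steepness,
    )
    write(
        "sensitivity.csv", lambda df, p: df.to_csv(p, index=False), sens.sensitivity
    )
    from .embeddings import embed_compound

    vecs = {c.id: embed_compound(c.smiles, ctable) for c in assay_compounds}
    X, y, gene_cols = assemble_cell_dataset(sens.cell_lines, sens.sensitivity, vecs)
    model, cv, ranking = train_ic50_model(
        X, y, gene_cols, folds=cfg.folds, seed=seed, n_repeats=1
    )

    train_matrix = predict_matrix(model, assay_compounds, sens.cell_lines, ctable)
    if cfg.target_lines:
        target_lines = list(cfg.target_lines)
    else:
        target_lines = designate_target_lines(
            train_matrix.probabilities, cfg.n_target_lines
        )

    candidates = [comp_by_id[cid] for cid in hit_ids]
    if not candidates:
        raise DataError("no candidate inhibitors survived the DPI screen")
    first = predict_matrix(model, candidates, sens.cell_lines, ctable)
    toxic = filter_by_target_lines(first, target_lines, cfg.threshold)

    known = {comp_by_id[cid].smiles for cid in hit_ids}
    fragments = []
    for mol_id in toxic:
        for frag in decompose_molecule(comp_by_id[mol_id].smiles):
            if frag not in known:
                known.add(frag)
                fragments.append(
                    CompoundRecord(id=f"FRAG{len(fragments) + 1:04d}", smiles=frag)
                )
    screened = [comp_by_id[cid] for cid in toxic] + fragments
    frag_lookup = {c.id: c for c in screened}
    write("fragments.smi", odio.write_smiles, fragments)

    matrix = predict_matrix(model, screened, sens.cell_lines, ctable)
    write(
        "prediction_matrix.tsv",
        lambda df, p: df.to_csv(p, sep="\t", index_label="molecule"),
        matrix.probabilities,
    )
    selective = selectivity_filter(
        matrix, cfg.threshold, target_lines, len(matrix.probabilities)
    )
    final = selective[: cfg.top_n]
    write(
        "selected_molecules.csv",
        lambda df, p: df.to_csv(p, index=False),
        pd.DataFrame(
            {
                "molecule": final,
                "smiles": [frag_lookup[m].smiles for m in final],
                "n_lines_hit": [
                    int((matrix.probabilities.loc[m] > cfg.threshold).sum())
                    for m in final
                ],
            }
        ),
    )

    report["stages"]["preclinical"] = {
        "n_records": len(sens.sensitivity),
        "cv_auc": cv.mean_auc,
        "n_important_genes": len(ranking.entries),
        "drivers_in_top40": len(set(ranking.top(40)) & sens.planted_gene_set),
        "n_drivers": len(sens.planted_gene_set),
        "target_lines": target_lines,
        "n_candidates": len(candidates),
        "n_toxic": len(toxic),
        "n_fragments": len(fragments),
        "n_screened": len(screened),
        "n_selective": len(selective),
        "final_molecules": final,
        "screened_ids": [c.id for c in screened],
        "elapsed_s": round(time.time() - t0, 2),
    }
    # strip remaining non-serializable intermediates
    for key in ("_prognostic", "_gene_ids", "_cohort_planted", "_targets"):
        report.pop(key, None)
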