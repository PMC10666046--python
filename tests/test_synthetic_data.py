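"""Generator contracts: determinism, planted-signal recoverability, null calibration."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from scipy import stats

from oncodisco.errors import ArgumentError
from oncodisco.synthetic_data import (
    AMINO_ACIDS,
    REFERENCE_GENE,
    generate_cohort,
    generate_compounds,
    generate_corpus,
    generate_interaction_world,
    generate_proteins,
    generate_sensitivity_panel,
    generate_tissue_panel,
)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

class TestCohort:
    def test_shape_and_invariants(self):
        cohort = generate_cohort(514, 1821, 10, 1.0, seed=7)
        assert cohort.expression.values.shape == (1821, 514)
        assert (cohort.expression.values.to_numpy() >= 0).all()
        assert cohort.planted_prognostic_genes <= set(cohort.expression.genes)
        assert len(cohort.planted_prognostic_genes) == 10
        assert (cohort.clinical["os_time"] > 0).all()
        assert (cohort.clinical["pfi_time"] > 0).all()
        assert cohort.clinical["patient_id"].is_unique
        assert REFERENCE_GENE in cohort.expression.genes

    def test_determinism(self):
        a = generate_cohort(50, 30, 5, 1.0, seed=11)
        b = generate_cohort(50, 30, 5, 1.0, seed=11)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert a.planted_prognostic_genes == b.planted_prognostic_genes

    def test_null_effect_outcome_independent_of_expression(self):
        cohort = generate_cohort(500, 100, 10, 0.0, seed=3)
        label = (cohort.clinical["os_time"] > cohort.clinical["os_time"].median()).astype(float)
        X = np.log(cohort.expression.values.T.to_numpy())
        corr = np.abs(
            np.corrcoef(np.column_stack([X, label]), rowvar=False)[-1, :-1]
        )
        # max over 100 null correlations at n=500: comfortably below 0.2
        assert corr.max() < 0.2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_patients=3, n_genes=10, n_prognostic=2, effect_size=1.0),
            dict(n_patients=10, n_genes=10, n_prognostic=10, effect_size=1.0),
            dict(n_patients=10, n_genes=10, n_prognostic=2, effect_size=-1.0),
        ],
    )
    def test_argument_errors(self, kwargs):
        with pytest.raises(ArgumentError):
            generate_cohort(seed=0, **kwargs)


# ---------------------------------------------------------------------------
# tissue panels
# ---------------------------------------------------------------------------

class TestTissuePanel:
    def test_planted_genes_carry_signal(self):
        # two-sample t statistics computed directly as the oracle
        panel = generate_tissue_panel(10, 10, 50, 5, 3.0, seed=2)
        X = np.log(panel.expression.values)
        tumor = panel.labels == "tumor"
        tstats = {}
        for gene in panel.expression.genes:
            t, _ = stats.ttest_ind(
                X.loc[gene, tumor.values], X.loc[gene, ~tumor.values]
            )
            tstats[gene] = t
        non_planted = [
            tstats[g] for g in tstats if g not in panel.planted_discriminative_genes
        ]
        for gene in panel.planted_discriminative_genes:
            frac_below = np.mean([tstats[gene] > t for t in non_planted])
            assert frac_below >= 0.9

    def test_class_ratio_and_invariants(self):
        panel = generate_tissue_panel(580, 102, 100, 10, 2.0, seed=1)
        assert (panel.labels == "tumor").sum() == 580
        assert (panel.labels == "normal").sum() == 102
        assert panel.planted_discriminative_genes <= set(panel.expression.genes)

    def test_shared_gene_namespace(self):
        genes = [f"G{i}" for i in range(30)]
        panel = generate_tissue_panel(
            20, 20, 30, 3, 1.0, seed=4, gene_ids=genes,
            discriminative_genes=genes[:3],
        )
        assert list(panel.expression.genes) == genes
        assert panel.planted_discriminative_genes == frozenset(genes[:3])

    def test_empty_class_rejected(self):
        with pytest.raises(ArgumentError):
            generate_tissue_panel(0, 10, 20, 2, 1.0, seed=0)


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

class TestProteins:
    def test_alphabet_closure_and_lengths(self):
        proteins = generate_proteins(100, (50, 300), seed=3)
        assert len(proteins) == 100
        alphabet = set(AMINO_ACIDS)
        for p in proteins:
            assert set(p.sequence) <= alphabet
            assert 50 <= len(p.sequence) <= 300

    def test_single_triplet_boundary(self):
        proteins = generate_proteins(1, (3, 3), seed=0)
        assert len(proteins) == 1 and len(proteins[0].sequence) == 3

    def test_triplet_distribution_uniform(self):
        # non-overlapping triplet counts over many draws vs uniform chi-square
        proteins = generate_proteins(10_000, (51, 51), seed=9)
        counts = {}
        for p in proteins:
            for i in range(0, 51 - 2, 3):
                kmer = p.sequence[i : i + 3]
                counts[kmer] = counts.get(kmer, 0) + 1
        observed = np.zeros(8000)
        idx = {a + b + c: i for i, (a, b, c) in enumerate(
            (x, y, z) for x in AMINO_ACIDS for y in AMINO_ACIDS for z in AMINO_ACIDS
        )}
        for kmer, n in counts.items():
            observed[idx[kmer]] = n
        _, pvalue = stats.chisquare(observed)
        assert pvalue > 0.01

    def test_min_length_rejected(self):
        with pytest.raises(ArgumentError):
            generate_proteins(5, (2, 10), seed=0)


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------

class TestCompounds:
    def test_validity_uniqueness_scale(self):
        compounds = generate_compounds(2921, seed=5)
        smiles = [c.smiles for c in compounds]
        assert len(smiles) == len(set(smiles)) == 2921
        for s in smiles[::97]:  # validity spot-check across the library
            assert Chem.MolFromSmiles(s) is not None

    def test_full_validity_small(self):
        for c in generate_compounds(150, seed=8):
            assert Chem.MolFromSmiles(c.smiles) is not None

    def test_determinism(self):
        a = generate_compounds(40, seed=5)
        b = generate_compounds(40, seed=5)
        assert [c.smiles for c in a] == [c.smiles for c in b]


# ---------------------------------------------------------------------------
# interaction worlds
# ---------------------------------------------------------------------------

class TestInteractionWorld:
    def test_invariants(self, world23):
        table = world23.score_table
        assert table["score"].between(0, 1).all()
        keyed = set(zip(table["protein_id"], table["compound_id"]))
        assert set(world23.positive_pairs) <= keyed
        assert not table.duplicated(["protein_id", "compound_id"]).any()

    def test_positive_scores_above_bulk(self, world23):
        table = world23.score_table
        pos = set(world23.positive_pairs)
        mask = [
            (p, c) in pos
            for p, c in zip(table["protein_id"], table["compound_id"])
        ]
        pos_scores = table.loc[mask, "score"]
        assert pos_scores.median() > table["score"].quantile(0.75)

    def test_hidden_rule_reproduces_labels_exactly(self, world23):
        # evaluating the latent dot-product rule directly recovers every label
        table = world23.score_table
        pos = set(world23.positive_pairs)
        for p, c in zip(table["protein_id"], table["compound_id"]):
            zp = world23.latents[f"protein:{p}"]
            zc = world23.latents[f"compound:{c}"]
            assert (float(zp @ zc) > world23.rule_cutoff) == ((p, c) in pos)

    def test_tiny_pos_fraction_reduces_to_bulk(self):
        proteins = generate_proteins(10, (30, 60), seed=1, composition_alpha=0.5)
        compounds = generate_compounds(20, seed=2)
        world = generate_interaction_world(proteins, compounds, 1e-9, seed=3)
        assert len(world.positive_pairs) == 0
        assert world.score_table["score"].max() <= 0.5

    def test_pos_fraction_range(self):
        proteins = generate_proteins(4, (10, 20), seed=0)
        compounds = generate_compounds(4, seed=0)
        for bad in (0.0, 0.5, 1.0):
            with pytest.raises(ArgumentError):
                generate_interaction_world(proteins, compounds, bad, seed=0)


# ---------------------------------------------------------------------------
# sensitivity panels
# ---------------------------------------------------------------------------

class TestSensitivityPanel:
    @staticmethod
    def _panel(n_driver, seed, n_lines=40, n_compounds=80):
        tissue = generate_tissue_panel(60, 10, 60, 5, 1.0, seed=seed)
        compounds = generate_compounds(n_compounds, seed=seed + 1)
        return generate_sensitivity_panel(
            tissue, compounds, n_lines, seed + 2, n_driver_genes=n_driver
        )

    def test_shapes_and_references(self):
        panel = self._panel(10, seed=5)
        line_ids = {ln.id for ln in panel.cell_lines}
        assert set(panel.sensitivity["line_id"]) <= line_ids
        assert len(panel.sensitivity) <= 40 * 80
        assert panel.sensitivity["success"].isin([0, 1]).all()

    def test_label_frequencies_match_logistic_rule(self):
        # recompute the rule from planted genes + recorded latents as oracle
        panel = self._panel(10, seed=7, n_lines=50, n_compounds=100)
        drivers = sorted(panel.planted_gene_set)
        expr = np.log1p(
            np.vstack(
                [ln.expression[drivers].to_numpy(dtype=float) for ln in panel.cell_lines]
            )
        )
        a = expr.mean(axis=1)
        a = (a - a.mean()) / a.std()
        a_by_line = {ln.id: a[i] for i, ln in enumerate(panel.cell_lines)}
        probs = np.array(
            [
                1.0 / (1.0 + np.exp(-4.0 * a_by_line[r.line_id] * panel.compound_latents[r.compound_id]))
                for r in panel.sensitivity.itertuples(index=False)
            ]
        )
        successes = panel.sensitivity["success"].to_numpy()
        # bucket by predicted probability; observed frequency must track it
        for lo, hi in [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)]:
            mask = (probs >= lo) & (probs < hi)
            if mask.sum() >= 100:
                assert abs(successes[mask].mean() - probs[mask].mean()) < 0.08

    def test_null_driver_set_gives_half_rate(self):
        panel = self._panel(0, seed=9)
        assert panel.planted_gene_set == frozenset()
        assert abs(panel.sensitivity["success"].mean() - 0.5) < 0.05


# ---------------------------------------------------------------------------
# corpora
# ---------------------------------------------------------------------------

class TestCorpus:
    def test_planted_tuples_retrievable(self):
        corpus = generate_corpus(
            ["BRAF", "EGFR"], ["vemurafenib", "sb203580"], ["cancer", "drug"],
            50, seed=13,
        )
        for doc_id, gene, inhibitor in corpus.planted_pairs:
            text = corpus.documents[doc_id]
            assert gene in text and inhibitor in text

    def test_placements_match_text_search(self):
        corpus = generate_corpus(
            ["KRAS", "TP53"], ["gefitinib"], ["target", "phase"], 80, seed=17
        )
        for doc_id, placed in corpus.planted_placements.items():
            tokens = corpus.documents[doc_id].replace(".", " ").split()
            for gene in placed["genes"]:
                assert gene in tokens
            for inh in placed["inhibitors"]:
                assert inh in tokens

    def test_zero_docs_rejected(self):
        with pytest.raises(ArgumentError):
            generate_corpus(["BRAF"], ["x1inib"], ["cancer"], 0, seed=0)
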