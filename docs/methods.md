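# Methods

`oncodisco` re-creates, as a tested and seeded software artifact, a
five-stage in-silico drug-discovery workflow for solid tumors: prognostic
target identification from patient expression and survival, a tumor/normal
expression filter, literature mining for each surviving target, drug–protein
interaction (DPI) prediction on learned sequence/substructure embeddings,
and an emulated preclinical cell-line screen ending in a selectivity filter.
Because the workflow's original inputs are large external databases, the
package ships a first-class synthetic-data layer that plants a known,
recoverable signal for every stage; all quantitative claims the test suite
makes are claims about recovery of those planted signals, not about real
tumors.

## Stage 1 — prognostic targets

*Model.* Expression is normalized per sample against a housekeeping
reference gene (each column divided by its GAPDH level; the reference row
becomes ones and the operation is idempotent).  Overall survival (OS) and
progression-free interval (PFI) are reduced to binary labels at the cohort
median: label 1 iff the observed time strictly exceeds the median, ties to
class 0 by default.  A multi-layer perceptron (two hidden layers 64/32,
rectifier activations, L2 weight decay 1.0) is trained under stratified
5-fold cross-validation and reports out-of-fold ROC-AUC.  We fit the
network with full-batch L-BFGS rather than minibatch SGD: at desk-scale
cohort sizes (hundreds to a few thousand rows) this is deterministic under
a fixed seed and markedly more stable than early-stopped Adam, which we
found to leave 0.05–0.10 AUC on the table at n = 1000.  Expression features
are `log1p`-transformed before standardization; the raw log-normal scale
otherwise lets a handful of extreme values dominate the scaler.

*Censoring.* The binarization uses observed time for every patient, with no
special handling of censored records; the synthetic cohort generator
exposes a `censoring` fraction (default 0, i.e. all events observed) so the
sensitivity of the median split to censoring can be probed, but the default
study condition ignores it, matching the workflow this package reproduces.

*Augmentation.* Small cohorts are enlarged with synthetic patients from a
tabular generative model.  The built-in backend is a per-class Gaussian
copula: within each label class, features are mapped to normal scores,
their correlation estimated (with a nearest-PSD guard), and samples are
inverted through empirical-quantile marginals — synthetic values therefore
never leave the observed per-column range, and the label is preserved as a
categorical column sampled at the observed class frequencies.  Cross-
validated AUC after augmentation is measured on the combined table, as in
the workflow being reproduced; synthetic rows are smoother than real ones,
so the absolute post-augmentation AUC is optimistic and only the *direction*
of the change is treated as meaningful.

*Ranking.* Gene importance is the absolute coefficient of a Lasso linear
regression of the binary label on standardized expression, with the penalty
chosen by 5-fold cross-validation (`LassoCV`, 40-point alpha grid).
Zero-variance genes are dropped; zero-coefficient genes are excluded from
the ranking.  OS and PFI rankings are merged by taking the union of each
list's top-k (default k = 25) and ordering by best rank across the two
lists, ties broken by larger summed importance, then lexicographically.

## Stage 2 — tumor/normal filter

The same classifier harness separates tumor from normal expression.  Genes
are ranked by held-out permutation importance averaged over folds; the
permutation score is **log loss**, not AUC, because with many redundant
discriminative genes the AUC saturates at 1.0 and permuting any single gene
shows no drop, whereas every informative gene still tightens prediction
margins.  A selector (`top_k` or `min_importance`) cuts the ranking to a
discriminative set, and the stage-1 list is intersected with it preserving
stage-1 order.

## Stage 3 — literature mining

A deterministic gazetteer/pattern NER stands in for a fine-tuned
transformer, with the same I/O contract (the original workflow's hand-
labeled corpus and weights are not available, and its reported accuracy is
therefore not reproducible here; an adapter interface allows a learned NER
to be plugged in later).  Co-occurrence counts are document-level — a cell
(gene, keyword) counts documents containing both as whole tokens, phrases
as consecutive tokens, case-insensitive — matching literature-query
semantics, with a total-mentions column summing the keyword columns.
Gene–inhibitor pairs require same-sentence mentions; inhibitors match a
lexicon, the "-nib" INN stem of kinase inhibitors, or a development-code
pattern (short letter prefix + ≥3 digits, e.g. sb203580).

## Stage 4 — drug–protein interactions

*Embeddings.* Proteins are tokenized as amino-acid 3-mers using k shifted
non-overlapping readings (offsets 0..k−1, incomplete tails dropped), the
ProtVec reading scheme; the vocabulary is bounded by the 8,000 possible
triplets.  Compounds are tokenized as Morgan circular-substructure
identifiers per atom and radius 0..1 in canonical atom order (the mol2vec
sentence), via RDKit's invariant hashing so identifiers are stable across
platforms.  Token vectors (d = 100) are learned by factorizing the windowed
positive-PMI co-occurrence matrix with a truncated SVD — the count-based
closed form of skip-gram with negative sampling — which is exactly
reproducible under a fixed seed.  An entity's vector is the *sum* of its
token vectors; out-of-vocabulary tokens contribute zero and are counted,
never silently dropped, keeping the sum contract total.

*Dataset.* Positives come from a curated interaction list; negatives are
"quartile negatives": pairs whose score in a score table falls at or below
the first quartile (linear-interpolation "type 7" definition, fixed for
reproducibility) of the full score distribution, restricted to the most
frequently scored compounds, with positives always excluded.  The ~5:1
negative:positive imbalance is kept; class weighting is exposed as config.
The justification for quartile sampling is the observed score structure:
known positives form a clean upper outlier of the bulk distribution
(minimum positive score above Q3 + 1.5·IQR of all scores), which the
synthetic world reproduces by construction.

*Synthetic world.* The hidden interaction rule is a latent dot product:
each protein's latent is a seeded random linear projection of its
amino-acid composition, each compound's latent a projection of its SMILES
token composition, both standardized across the population, and the top
`pos_fraction` of pair utilities are positive.  The latents are never shown
to the models — but because they are functions of low-dimensional
*observable* composition, and because across-entity variation of token
counts then lies on a low-dimensional manifold, any full-rank sum-embedding
preserves a learnable proxy of the rule.  For the same reason the world's
default proteins draw per-protein residue frequencies from a Dirichlet
(α = 0.5): with strictly uniform residues the compositional signal would be
sampling noise only.  Positive pairs' scores are drawn from a high band
(0.78–0.97) and the bulk from a scaled Beta(2,5) (≤ 0.5), producing the
outlier structure above.

## Stage 5 — preclinical emulation

Rows are (cell-line expression ⊕ compound vector) with a binary IC50-success
label; the synthetic label is Bernoulli with probability
`sigmoid(steepness · a · b)` where `a` is the line's standardized mean
log-expression of planted driver genes and `b` a standardized projection of
the compound's SMILES composition (steepness 4 by default, giving a Bayes
AUC comfortably above the 0.8 the strong preset asserts; zero driver genes
give exactly chance).  The trained classifier yields a molecules × lines
probability matrix; molecules must strictly exceed the probability
threshold (default 0.9, strict per the workflow's wording) on **every**
required target line; surviving molecules are decomposed at BRICS
bond-breaking sites (fragments canonicalized, dummy attachment points
stripped, deduplicated; an unbreakable molecule returns itself) and the
fragments are appended to the candidate set; the selectivity filter then
ranks candidates by the count of all lines hit above threshold (fewest
first — most selective), ties by lower mean off-target probability, then id.

*Target-line designation.* When no required lines are configured, the
pipeline designates them from the data: the line whose predictions over the
training compounds spread the most (the model can discriminate on it), plus
the line(s) whose prediction profiles correlate best with it — an in-silico
analogue of choosing a pair of commonly used, concordantly responding
reference lines.  A config list overrides this.

## Pipeline orchestration

One global seed derives per-stage seeds as a stable SHA-256 hash of
(seed, stage name), so any stage can be re-run in isolation with identical
results.  Each stage writes self-describing text outputs before the next
starts; the run report records per-stage metrics and SHA-256 digests of all
outputs, and identical config + seed reproduce identical digests.  The
config is validated against a versioned schema before execution (unknown
keys rejected, all range violations listed at once, resolved config echoed
to the report).

## Default study conditions and problem sizes

The strong synthetic preset uses a 500-patient × 120-gene cohort with 10
planted prognostic genes at total log-hazard spread 2.0 (each planted gene
weighted `effect/√n_planted`; exponential OS/PFI times with log-linear
dependence on planted expression); a 300+180-sample tissue panel sharing
the cohort's gene namespace with the cohort's planted genes re-planted at
log-shift 2.0; a 250-compound / ~50-protein interaction world at 5%
positives; and a 36-line × 122-compound sensitivity panel.  These sizes are
chosen so the full pipeline is a minute-scale desk experiment while every
planted signal stays comfortably recoverable; the standalone recovery
drills use larger cohorts (e.g. 2,000 × 200 for the Lasso drill) where the
statistical claim needs them.  The weak preset lowers effect sizes
(0.6 / 0.6 / steepness 1.5) to probe graceful degradation.

## What the generators do and do not emulate

They emulate: log-normal expression with per-sample library-size factors
and a stable housekeeping gene; survival times whose hazard is log-linear
in planted expression; mean-shifted tumor markers; a compound library from
a closed SMILES template grammar (rings, chains, amide/ester linkers,
branches) that is valid by construction; score tables with outlier
positives; logistic expression-driven drug sensitivity; and abstracts with
planted entity mentions.  They do **not** emulate batch or platform
effects, censoring-informative dropout, realistic medicinal chemistry
beyond syntactic validity, correlated gene modules, or the linguistic
variety of real abstracts.  Passing tests therefore demonstrate that each
stage recovers the signal class it is designed for under its stated noise
model — not performance on real cohorts or libraries.

## Numerical choices and degenerate inputs

Quantiles are linear-interpolation type 7 throughout.  All probability
thresholds are strict (>).  Median-split ties go below by default
(configurable).  Ranking ties break by feature id; merged-list ties by
summed importance then id; selectivity ties by off-target mean then id.
Degenerate inputs raise typed errors: identical survival times, a
single-class median split, a missing or non-positive reference gene (the
offending samples are named), folds that cannot contain both classes,
unparseable SMILES (the input is named), an empty embedding corpus, a
quartile rule that yields no negatives.  Zero-variance genes are dropped
from rankings; an all-zero Lasso fit returns an empty ranking with a
warning rather than an error.

## Known limitations

Absolute AUCs on synthetic data are not comparable to values obtainable on
real cohorts; the post-augmentation AUC in particular is measured on mixed
real+synthetic folds and is optimistic by design.  Permutation importance
with log loss measures marginal, not conditional, contribution and will
split credit across strongly correlated genes.  The gazetteer NER cannot
discover entities outside its lexicon/patterns.  The copula augmenter
cannot extrapolate beyond observed per-column ranges, and the embedding
factorization ignores corpus order beyond the co-occurrence window.
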