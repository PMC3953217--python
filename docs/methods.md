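# Methods

## Data model

The unit of analysis is the *unique interaction*: an unordered pair of
protein identifiers with merged annotations from all source records.
Identifiers are the raw MITAB column-1/2 primary ids with the database
prefix stripped (`uniprotkb:P04637` → `P04637`); no cross-database id
mapping is attempted, so records that refer to one protein under two
accession schemes stay distinct.  Self-interactions are kept in the
dataset but excluded from motif analysis, where a triangle requires three
distinct proteins.

Detection-method and interaction-type annotations live in psi-mi-style
controlled vocabularies: rooted DAGs over `is_a` edges.  Only `is_a` is
honoured; `relationship:` lines (`part_of` etc.) and obsolete terms are
ignored, and no virtual super-root is added (terms in disconnected
namespaces have similarity 0).  Annotation *closure* adds every ancestor
of an annotated term and includes the term itself; the `ancestors` query
excludes it.  Closure is monotone and idempotent, which the tests assert.

Type-specific enzymatic assays (the "enzymatic study" subtree: phosphatase
assay, protease assay, ...) are special: they imply an interaction type
directly.  A user-supplied assay→type table adds those types during
ingest, mirroring how such assays are interpreted in curated resources.
The same subtree is then excluded from the feature matrix — predicting
"dephosphorylation" from "phosphatase assay" would be circular.

## Feature construction

Features are binary memberships in the *closed* method sets.  Columns are
dropped when (i) they fall in the excluded assay subtree, (ii) fewer than
`min_count` (default 200) interactions carry them — counted on closed
sets, since the features themselves are closed-set memberships — or
(iii) every interaction carries them (top-level terms such as "interaction
detection method" say nothing).  Construction is deterministic and
independent of input order; columns are sorted.

## Enrichment

For each retained method and each interaction type, the number of
interactions carrying both is scored against the hypergeometric
distribution: `p_enrich = P[X ≥ k]`, `p_deplete = P[X ≤ k]`.  The two
tails share the point mass at `k` and sum to at least 1.  The universe is
the set of interactions in the feature matrix — the data actually
analysed — rather than the raw record pool.  Raw tails are the primary
output; Benjamini–Hochberg q-values are attached as an extra convenience
column.  The degenerate empty universe (N = 0) returns both tails as 1.

## The per-type classifier

One binary logistic model per type, fitted by unregularized maximum
likelihood (lbfgs, tolerance 1e-8).  Binary features on a few hundred
training examples can be perfectly separable; when the optimizer fails to
converge or any coefficient exceeds 30 (probabilities pinned to 0/1 —
past any interpretable log-odds), the model is refitted with a tiny ridge
penalty (λ = 1e-6) and flagged `stabilized_`.  The estimator follows
scikit-learn conventions and composes with sklearn model selection.

Training sets: positives are all interactions closed-annotated to the
type.  The negative target size is max(|positives|, 100).  Negatives are
drawn first from interactions carrying a *different* specific type
(multi-type interactions are barred from serving as negatives for any
type they carry), subsampled uniformly if over target, then topped up
from untyped interactions with at least 4 *direct* detection methods —
direct rather than closed, because closure inflates every count by
construction.  The other-type-first composition order and the ≥4-method
filter are configurable.

Evaluation: 20 independent repeats of stratified 10-fold
cross-validation, a fresh negative draw per repeat.  Stratification
prevents one-class folds at positive-set sizes near 30, where plain
random folds would frequently fail.  Each repeat pools its out-of-fold
scores into one AUC (rank-statistic with tie correction); the reported
figure is the mean over repeats.  A permutation-null mode shuffles labels
within each repeat's training set and should yield AUC 0.5 — shuffling
type annotations across the whole dataset instead would leak the
composition bias of the negative-set design (the random pool is
better-annotated by construction) and sit near 0.55 without any
method→type signal.

The deployed cutoff per type maximizes sensitivity + specificity on the
ROC of the scores pooled across all repeats, with ties broken toward
higher specificity; the final model is then refitted on a full training
set.  Deriving the cutoff from out-of-fold scores avoids training-set
optimism without holding out data from the final fit.  Candidate
thresholds are midpoints between consecutive unique scores plus one
sentinel below and above, so a separable score set yields a mid-gap
cutoff.

## Validation

**Gold standards.**  Curated pair lists (kinase–substrate,
ubiquitination) are mapped into the analysis universe; pairs already
psi-mi-annotated to the type are removed first, as they carry no
independent information.  "Accuracy" is reported as precision restricted
to the mapped universe — stated prominently because the natural-language
term is ambiguous.  Enrichment reuses the same hypergeometric routine as
the method–type table.  When raw scores are supplied, a gold-versus-rest
AUC over the universe is also computed; the universe is an explicit
argument rather than a hidden default.

**Semantic similarity.**  Protein-level similarity is the symmetric
best-match average of Resnik term similarities (IC of the most
informative common ancestor; natural-log IC from closure-based
annotation frequencies; each term is its own ancestor, so
resnik(t,t) = IC(t)).  BMA is the conventional set-level aggregation; the
aggregation is a single switchable strategy should another be preferred.
Each type's edge-similarity distribution is compared to 10 equal-size
random draws of interacting pairs with a one-sided rank-sum test
(typed > random), and the *maximum* p over draws — the least favourable —
is reported.  Pairs with an unannotated protein are skipped.

**Pathway profiles.**  Pathways are consumed from a flat TSV
(pathway, subcategory, member pair, optional native type label) — a
documented flattening of pathway XML; no live API client.  Pathways with
fewer than 10 typed member interactions, then subcategories with fewer
than 5 pathways, are dropped.  Pearson r between type-count vectors is
computed for every pathway pair and the intra-/inter-subcategory r
distributions compared by a one-sided rank-sum test.  Native labels, when
present, run through the same machinery as a parallel call set.

## Motifs

The typed network has one node per protein and one edge per called pair,
labeled with its set of called types.  The census enumerates every
triangle once (ordered node triples) and, for each choice of one type per
edge, increments the count of the sorted type-triple; an edge with k
types contributes k assignments.  A strict mode counts each triangle once
under its lexicographically smallest triple.

The null model rewires each type's subnetwork separately with
Maslov–Sneppen double-edge swaps — 10 × |E_t| accepted swaps, a standard
mixing heuristic, configurable — and recombines by union.  Swaps
guarantee simple graphs while preserving each type's degree sequence
*exactly*, which the tests assert; subnetworks with fewer than two edges
are returned unchanged, and a swap quota that cannot be met (tiny or
near-complete subgraphs) leaves a partial rewire that still preserves
degrees.  The swap routine is implemented in-module with batched random
draws; it performs the same uniform-edge-pair chain as the textbook
algorithm.  Significance is empirical enrichment only,
p = (1 + #{null ≥ observed}) / (n_random + 1) over 500 randomizations by
default; the +1 keeps p strictly positive.  Whether recombination may
merge two types onto one pair is a modelling choice; the union semantics
used here is the permissive reading.

## Synthetic data

The generators define the study conditions for every test.  The standard
interaction fixture: 5,000 unique interactions over 1,500 proteins, 12
candidate detection methods, 3 specific types each driven by its own
block of 3 methods at log-odds 3.0 over a baseline method probability of
0.3; 30% of interactions carry a latent type, of which 25% are labeled in
the MITAB type column (the rest stay at "physical association",
mimicking — at a testable rate — the extreme labeling sparsity of real
compendia, to which the `labeled_fraction` knob scales down).  10% of
pairs emit a redundant second record to exercise deduplication, and 5% of
latent-cleavage interactions carry a protease-assay method to exercise
the assay→type path.  Methods are conditionally independent given the
latent type, which makes the logistic model well-specified: the true
coefficient of a causal method equals its generating log-odds, the basis
of the parameter-recovery check.

What the generators do *not* emulate: the real psi-mi topology (130
methods, 29 types), realistic degree distributions, correlated detection
methods, study bias, or identifier noise.  Passing tests therefore show
that the machinery is correct and calibrated under its own assumptions,
not that comparable AUCs would be reached on a real compendium.

Other fixtures: a planted 6-clique of one type over a sparse typed
Erdős–Rényi background (motif recovery); gold standards as noisy subsets
of truth-typed pairs with controllable recall and precision; pathway
memberships drawn from per-subcategory Dirichlet type-rate vectors
(structured) or a shared uniform vector (null); annotation corpora from a
random GO-like tree with one branch reserved per type, so same-type
proteins share deep terms (structured) or draw uniformly (null).  All
generators are deterministic per seed and byte-stable.

## Pipeline

Stages run in a fixed order (ingest, features, enrich, train, predict,
validate, motifs); each stage's random substream derives from the single
run seed via seed-sequence spawning, so artifacts and the manifest of
content hashes are byte-identical across same-seed runs.  Stages can be
re-run individually against a run directory; missing optional inputs
(gold standards, pathways, annotations) skip their validation with a
warning rather than failing the run.  A failing stage leaves a `FAILED`
marker naming it, next to whatever artifacts were already written.

Default problem sizes (the standard fixture, 20×10-fold CV, 500 motif
randomizations, 200 randomizations in the recovery experiments) keep a
full run within a few minutes on one CPU.

## Known limitations

- No cross-database identifier mapping; the same physical interaction
  under different accessions is counted twice.
- Detection-method features only; protein-level annotations are not used
  by the classifier (a natural extension, deliberately out of scope).
- Undirected edges throughout: enzyme→substrate direction is not modeled,
  in the motif census in particular.
- Only 3-node/3-edge motifs; no larger patterns.
- The negative-set definition assumes untyped, well-annotated
  interactions are mostly true negatives for every specific type; at real
  labeling sparsity some are false negatives, which biases recall
  estimates downward.
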