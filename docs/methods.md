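# Methods

## Problem and model

Public specialist outpatient referrals in this setting are triaged into
three urgency categories using Clinical Prioritisation Criteria (CPC):
per-condition, per-age-group guideline texts describing which clinical
findings warrant category 1, 2 or 3. The engine mirrors the clinical
workflow: resolve the age group, resolve the condition (CPC), then pick the
category whose criteria text best matches the referral's medical terms.

Two prediction problems are therefore chained:

1. **CPC prediction** (multiclass over 20 adult / 13 paediatric ENT
   conditions) — needed for the ~90% of referrals that arrive without a
   valid CPC label. Five families are implemented behind one interface:
   a content-based similarity ensemble (no training data required), a
   10-nearest-neighbour similarity vote, supervised multiclass
   classification, self-training, and catalog-seeded k-means.
2. **Category prediction** — the referral's terms are scored against the
   resolved CPC's three per-category text units with a single metric;
   the best unit's category wins. CPCs with a mandatory category
   short-circuit this step.

Because the historical categories the engine is compared against were
themselves assigned inconsistently, evaluation reports a *level of
agreement* (fraction matching) with a 3×3 confusion matrix and per-category
precision/sensitivity, never an "accuracy against truth". Uniform random
ternary assignment scores 1/3 on this scale.

## Text preprocessing

Referral text (or each extracted entity's text) is lowercased, stripped of
everything outside `[a-z]` and whitespace (numbers and punctuation are
removed, not spelled out), tokenized on whitespace, filtered against a
fixed English stopword list (scikit-learn's, configurable) and stemmed with
the classic Porter algorithm, implemented in `cpctriage._porter` and pinned
against the algorithm's canonical examples so token-level tests are stable.
The same cleaning is applied to entity text and (by the generator's
construction) is idempotent on catalog tokens, keeping the two sides of
every similarity comparison consistent.

Medical-entity ingestion follows an extractor-agnostic contract: any list
of `(text, category, type, score)` records works. Entities are kept when
their score is ≥ 0.5 (boundary inclusive) and their (category, type) pair
is in the curated allow-list (diagnosis names; generic and brand medication
names; treatment and procedure names; anatomical directions). A
deterministic longest-match dictionary extractor is included so the
pipeline runs without any external NER service; referrals whose entities
all fail the filter fall back to cleaned raw text so similarity is never
computed on an empty document.

Age group: completed years at the submission date, under 16 → paediatric,
16 and over → adult (the exact 16th birthday counts as adult); cutoff
configurable.

## Similarity ensemble

Cosine and Euclidean operate on raw term-count vectors over the union
vocabulary (no TF-IDF, no length normalization); Jaccard on term sets;
Levenshtein on the space-joined token strings in stored order (the join
order is pinned because the edit distance is order-sensitive). The
Levenshtein matrix is computed row-wise in numpy; tests verify it against
the naive recursion exhaustively (all pairs ≤ length 4 over a 3-letter
alphabet) and against an independent alignment library on random strings.

The ensemble adds similarities and subtracts distances. The edit distance
is normalized by `max(len a, len b)` — the true maximum possible distance —
by default; division by `len a + len b` is retained as an option since the
published score uses that form. The ensemble mixes bounded similarities
with an unbounded Euclidean term, so on long documents Euclidean can
dominate; this is implemented as published and left to the weights to
balance. One correction is applied: the published Euclidean-to-similarity
conversion `1/e^(−d)` *grows* with distance, contradicting its stated
purpose, so the KNN family uses `e^(−d)` (equivalently `1/e^d`).

Ensemble weights are the four metrics' categorisation accuracies measured
on referrals with a valid attached CPC (unit weights until estimated). If
all four accuracies are zero the weights are returned with a warning —
they cannot rank candidates.

Ties everywhere (argmax over CPCs, KNN votes, nearest centroid) break
toward the ascending `cpc_id`; category ties break toward the lower
(more urgent) category — the patient-safety-conservative choice.

## Count features and the trainable families

KNN, supervised, self-training and k-means share one feature space:
unigram + bigram counts of the medical terms, columns kept when their
document frequency is ≥ `min_doc_count` (default 30, the large-corpus
setting) and ≤ `max_doc_fraction` (default 0.8) of documents, columns in
lexicographic order. On desk-scale corpora `min_doc_count` must be lowered
(the pipeline helpers default to 1) or the vocabulary empties — the
filtering error says so explicitly.

- **KNN**: top-10 labeled neighbours by `exp(−Euclidean)` similarity,
  keeping only similarity > 0 (which excludes underflow at extreme
  distances); per-CPC vote weight is the sum of its neighbours'
  similarities; no qualifying neighbour yields an explicit no-prediction
  sentinel rather than a guess.
- **Supervised**: any standard learner (logistic regression, linear SVM,
  SGD perceptron, random forest, gradient boosting, MLP) behind a
  fit/predict/confidence contract, optionally wrapped in one-vs-rest,
  one-vs-one (n(n−1)/2 binary problems) or error-correcting output codes.
  Confidence is `predict_proba` when available, else a softmax over the
  decision function — always a probability simplex per row. All
  stochastic learners take an explicit seed. Hyperparameters pass through
  as an opaque map; no grid search is bundled.
- **Self-training**: train on the labeled pool, move every unlabeled row
  whose top-class confidence ≥ 0.75 (deliberately above the plain 0.5
  decision threshold) into the pool under its pseudo-label, repeat until
  an iteration adds nothing or `max_iter` (default 10). The pool is
  monotone non-decreasing and every addition is logged
  (iteration, row, label, confidence).
- **Seeded k-means**: Lloyd's iterations with k fixed to the CPC count of
  the age group and centroids initialized at the vectorized CPC texts, so
  each cluster is bound to a CPC from the outset and assignment doubles as
  prediction. Empty clusters keep their previous centroid (k never
  degenerates); the within-cluster sum of squares is recorded per
  iteration and is non-increasing; convergence when the maximum centroid
  movement < 1e-4 or after 300 iterations (conventional defaults). A seed
  text that vectorizes to all zeros is a configuration error reported with
  the CPC's id; the pipeline therefore fits the vectorizer on referrals
  *plus* catalog texts, which also keeps zero-frequency conditions
  predictable. Adult and paediatric models are always trained separately.

Stratified k-fold evaluation preserves class proportions (per-class fold
counts differ by ≤ 1) and tests every row exactly once; 1,689 rows split
5-fold give a largest test fold of 338 (20%).

## Synthetic data: what it emulates, and what it does not

No real referrals or real CPC text are bundled (privacy and licensing);
the only real statistics carried are the published labeled-set class
frequencies, used as a sampling profile (including its zero-frequency
conditions, which stay in the catalog and remain predictable).

The generator builds, per condition, a core vocabulary disjoint from every
other condition's, split into *condition terms* shared by all three
category units and per-category *qualifier terms* — mirroring real
referrals, which share condition vocabulary whatever their urgency and
differ in qualifying findings. The keyword representation is exactly these
units; medical terms add a morphological variant; criteria words add
shared filler, emulating the noisier full criteria text. Vocabulary words
are generated to be Porter-stemmer fixed points so preprocessing leaves
both sides of a comparison aligned.

Referrals sample a condition from the class profile, a category from its
units (mandatory-category conditions always imply their category), and mix
unit terms (in criteria wording order — term order is what makes the
character-level comparison meaningful) with shared background noise at
`signal_fraction` (default 0.8). `typo_rate` (default 0.05) is the
per-character probability of a single-character substitution, insertion or
deletion: low rates emulate isolated typos, high rates the run-together
spelling variants that defeat token matching while leaving character-level
similarity largely intact. A `labeled_fraction` (default 0.097) of
referrals carries its condition name as a CPC label; the historical
category differs from the CPC-implied one with probability
`historical_noise` (default 0.3, reflecting the substantial disagreement
between guideline-implied and historically assigned categories). Dates are
generated consistent with the age group; roughly two-thirds of referrals
are adult. Everything is deterministic per seed.

What passing tests on this corpus show: the pipeline wiring is correct
(noise-free corpora are recovered exactly by the similarity and seeded
k-means predictors and ≥90% by KNN), the degradation ordering under typos
is as claimed (character-level beats token-level at a 0.3 per-character
rate), and the evaluation arithmetic is exact. What they do not show:
performance on real clinical language — real referrals have correlated,
polysemous vocabulary, entity-extraction errors, and label noise that is
anything but uniform, so absolute agreement numbers on synthetic corpora
do not transfer.

## Numerical and design choices

- Levenshtein normalization defaults to `max_len`; `sum_len` is selectable.
- Empty documents: cosine/Jaccard 0, distances from the zero vector —
  degenerate referrals never crash the pipeline.
- CPC label matching is exact after normalization (lowercase, punctuation
  stripped, whitespace collapsed) — a membership check, not fuzzy matching,
  which could silently re-label referrals.
- Combined CPC text concatenates category units in ascending category
  order (pinned for the order-sensitive edit distance).
- `historical_noise` is the probability the historical category *differs*
  from the CPC-implied one (flips go to a uniformly chosen different
  category), so agreement against historical labels under perfect
  prediction is 1 − noise.
- Batch triage collects per-referral failures and continues; results carry
  whether each CPC was given or predicted, and by which method.
- Problem sizes in the test suite and acceptance script (2,000-referral
  recovery corpora, 5 × 400 robustness corpora, 100,000-draw baseline)
  were chosen so the full suite completes in about a minute on one CPU
  while keeping binomial 3σ bands tight enough to be meaningful.

## Known limitations

- The ensemble's unbounded Euclidean term can dominate on long documents
  (implemented as published; use the weights or a single metric).
- Supervised/self-training families need every predicted class present in
  the labeled pool; classes absent from it are unreachable (KNN and the
  similarity/k-means families do not have this limitation).
- The generator's disjoint-core-vocabulary assumption makes CPC prediction
  easier than on real data; it is a wiring oracle, not a difficulty
  benchmark.
- Only an ENT-shaped fixture catalog is generated; the schema is
  specialty-agnostic but no other catalog ships.
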