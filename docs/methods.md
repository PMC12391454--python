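# Methods

This note documents the models, conventions and design choices behind
`genshift`: what the synthetic generator does and does not emulate, the exact
definitions of the divergence statistics, the classifier and experiment
protocol, and the numerical decisions that matter for reproducing results.

## Synthetic multi-institution corpus

The generator emulates a multi-center procedure registry: records are
`(institution_id, free_text, code_label)` triples, every institution shares
one global label set, and institutions differ in their label mix and in
their writing habits.

**Label mixes (label shift).** A common case-mix base `g ~ Dirichlet(2·1_K)`
is drawn once per corpus; each institution's mix is
`p_i ~ Dirichlet(label_concentration · K · g)`. The hierarchical form
captures that popular procedures are popular nearly everywhere while still
giving each site substantial idiosyncratic skew; fully independent mixes
would make label popularity uncorrelated across sites, which no registry
restricted to commonly shared codes looks like. `label_concentration`
(default 1.0) is the per-institution skew dial: large values pull every site
toward the common mix. Planted outliers (`outlier_institutions`) override a
site's mix, either with an explicit probability vector or with a scalar mass
concentrated on a designated label subset (a "pediatric-focus" style
anomaly); ground truth records the subset.

**Text assembly (covariate shift).** Each of up to 48 labels has a phrase
template in the style of real procedural text: optional laterality, a
distinguishing modifier (total/partial, open/laparoscopic, ...), site tokens,
an action-synonym slot, optional boilerplate tail and an optional
surgical-code digit group (`21,050,`). Institutional variation enters as:

- *jargon*: with probability `private_vocab_fraction` (default 0.5) the
  modifier+action phrase is replaced by a local shorthand word. Each label
  has a finite pool of 6 plausible jargon variants and each institution
  commits to one, so two sites coincide on a label's shorthand with
  probability 1/6 — local vocabulary recurs across subsets of sites rather
  than being globally unique, which is what makes multi-site training cover
  part of a held-out site's vocabulary;
- *private boilerplate*: each institution carries an inventory of
  `round(16 · private_vocab_fraction)` pseudo-word boilerplate tokens used in
  tails, so observed vocabulary divergence is graded in the knob rather than
  saturating;
- *style intensities*: per-institution boilerplate frequency and abbreviation
  tendency perturb word *distributions* without changing supports, so the
  zero-noise configuration yields identical vocabularies at every site;
- *underspecification*: the distinguishing modifier is dropped with
  probability `modifier_drop_rate` (default 0.2), leaving text consistent
  with a sibling label — classification of such records depends on the label
  prior, which is exactly where single-site and pooled models diverge.

**Noise.** Acronym substitution (rate 0.15; acronyms expandable by the
maximal preprocessing level), per-word misspellings at
`misspell_word_rate = 0.10` (single character substitution or adjacent
transposition on alphabetic tokens of length ≥ 4, recorded per record so
noise statistics and spell-corrector behavior are exactly checkable), mixed
casing, inserted stop words, punctuation. All constants above are the
package's emulation of a registry whose text shows ~10% misspelled words.

**Ground truth.** The generator returns per-institution label distributions,
per-(institution, label) expected clean word distributions (noise-free,
minimal-normalized), the injected misspelling map, abbreviation map and
private vocabularies. This enables parameter-recovery tests (empirical vs
analytic divergences) and exact noise accounting.

**What passing tests do not show.** The generator produces short, templated,
single-clause notes with a closed vocabulary of a few thousand types;
real procedural text has longer clauses, richer synonymy, context-dependent
abbreviations and billing-error label noise. Results on synthetic corpora
demonstrate that the pipeline's statistics behave directionally as intended
(transfer degrades under shift, divergence predicts degradation, planted
structure is recoverable); they do not calibrate absolute accuracies for any
real registry.

## Preprocessing levels

Strictly cumulative; each level is idempotent and emits lowercase
alphanumeric tokens only.

- *minimal*: commas between digits are deleted (so `27,447` → `27447`
  survives as an identifier), every other non-alphanumeric character becomes
  a space, text is lowercased and split; stop words (packaged fixed list)
  are removed; standalone `1`..`10` become `one`..`ten` (a literal reading —
  other numerals untouched).
- *spell*: tokens absent from the reference word list are corrected by (a) a
  curated misspelling dictionary, else (b) the *unique* reference word within
  one edit — substitution, insertion, deletion or adjacent transposition;
  ties or distance > 1 leave the token unchanged. Conservatism avoids
  cascading corrections; digit-bearing tokens are never touched.
- *maximal*: tokens found in the abbreviation table are replaced by their
  multi-word expansions (`tka` → `total knee arthroplasty`).

Lexicons are plain TSV files (`stopwords.tsv`, `misspellings.tsv`,
`abbreviations.tsv`, `wordlist.tsv`); the packaged versions cover the
synthetic templates and can be swapped for tables derived from a medical
lexicon.

## Divergence statistics

- Distributions are compared on the union support after additive smoothing
  with `ε = 1e-9` and renormalization; KL is in natural log (nats). Both
  choices are recorded in every matrix's metadata sidecar.
- Direction: `metric(A→B)` quantifies applying institution-A-trained models
  to institution-B data and is computed as `D(P_B ‖ P_A)` — the expected
  extra code length of B's data under A's reference distribution. The
  convention is configurable and logged.
- `KLD_word` uses token frequencies (with multiplicity), not per-record
  unique-word indicators: a probability distribution over words requires
  frequencies.
- Composite KLD: the default `product` strategy multiplies the label
  divergence by the label-weighted mean of per-label word divergences,
  `w_c ∝ (p_A(c)+p_B(c))/2` renormalized over labels observed at both sites;
  labels unobserved at either site are excluded and counted. A
  `weighted_sum` strategy (word term alone) is provided as the alternative
  composite; the choice is recorded in output metadata.
- **Estimator regime.** With near-zero smoothing, the plug-in KLD estimator
  diverges whenever one side has an empty cell where the other has mass:
  a label with true probability ~1e-5 is empirically indistinguishable from
  an absent label at n = 5000, and the smoothed log-ratio then overstates
  the divergence by O(ln(1/ε)). Parameter-recovery claims therefore only
  hold in the well-sampled regime (`n · min p ≫ 1`), and the recovery tests
  plant label mixes satisfying it. On observed corpora this behavior is
  intentional: support differences *are* divergence.

## Classifier

TF-IDF over preprocessed tokens feeding a feed-forward network with ReLU
hidden layers (500, 250) and a softmax output over the shared label set,
trained with Adam under cross-entropy. The implementation is sklearn's
`MLPClassifier`; regularization is an L2 penalty (`alpha = 1e-4`) rather
than dropout, which that backend does not provide. Training defaults:
learning rate 1e-3, batch size 128, up to 30 epochs with early stop when the
loss plateaus (3 epochs within 1e-3). Fitting is deterministic given
`random_state`.

TF-IDF dialect (recorded in model metadata): smoothed idf
`ln((1+n)/(1+df)) + 1`, raw term counts, L2-normalized rows; the vocabulary
is fit on the training documents of each model separately (transfer realism:
a site cannot know another site's vocabulary), and unseen test tokens are
ignored.

## Experiment protocol

- *pairwise*: one model per (institution, level) trained on the entire
  institution, evaluated on every other institution's full data. Self cells
  use stratified 5-fold cross-validation (mean of fold metrics) so no record
  is ever scored by a model that saw it; transfer cells use the full-data
  model.
- *pooled 80:20*: five disjoint folds, each holding out a stratified 20%
  within every institution; one combined model per fold; per-institution
  metrics are fold means.
- *leave-one-institution-out*: one model per held-out institution.

Micro-averaged F1 equals accuracy for single-label multiclass prediction
(pooled FP = pooled FN); the identity is asserted on every evaluation cell at
construction. All randomness (splits, network init) derives from one
experiment seed through labeled SHA-256 seed derivation; a full study is
reproducible bit-for-bit, and every model's training-set fingerprint plus
every cell's test indices are kept in an audit log checked by leakage tests.

## Clustering and outliers

- Directed composite-KLD matrices are symmetrized by the element-wise mean
  with the transpose before clustering.
- k-medoids is PAM: greedy build plus best-improvement swap to convergence,
  restarted from 8 seeded random initializations in addition to the build
  (single-start PAM can stall in a local optimum even on four points); the
  lowest-cost solution wins, ties break toward the lowest index.
- The elbow rule scans k over (2, 25) (capped at n−1) on the within-cluster
  sum of *squared* dissimilarities, extends the curve one point below the
  selection range so a drop into the smallest candidate k is visible, and
  picks the k of maximum perpendicular distance to the endpoint chord (ties
  toward smaller k; a non-monotone curve falls back to the maximum second
  difference with a warning).
- Classical (Torgerson) MDS embeds institutions in 2-D: double-center the
  squared dissimilarities, take the top-2 eigenpairs, scale by √eigenvalue;
  orientation is fixed by requiring each axis's largest-magnitude coordinate
  to be positive; dominant negative eigenvalues trigger a non-Euclidean
  warning.
- Outliers: within each cluster of size ≥ 2, an institution is flagged when
  its mean divergence to fellow members exceeds the cluster mean by
  `threshold_sd` (default 1.0) population SDs; singleton-cluster members are
  always flagged and sort first.

## Problem sizes

The package's full-scale study — the default `demo_config(scale="full")`
used by the acceptance script and the directional tests — is 6 institutions
× 1500 records with 16 labels, two preprocessing levels and all three
designs (~100 model fits, a few minutes on one CPU). The scaled-down
`scale="small"` configuration (4 × 400, one level, pairwise) backs quick
end-to-end and determinism checks. Unit tests run on corpora of tens to
hundreds of records with a small (64-unit) network that converges reliably
at that scale.

## Known limitations

- Real cSpell-style correction and curated medical lexicons are richer than
  the packaged dictionary + edit-distance-1 rule; ambiguous abbreviations are
  expanded context-free.
- The composite statistic's two variants bracket plausible definitions of a
  label-normalized word divergence; neither is canonical.
- Absolute performance numbers depend on the generator's template mechanism;
  only directions and orderings (self > non-self, pooled/LOIO gains,
  negative divergence-performance correlation) are asserted.
- Label noise (billing errors) is not modeled.
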