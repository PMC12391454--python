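# genshift

Cross-institution generalizability of free-text procedure-code classifiers.

## The problem

Clinical procedure notes ("Left total knee replacement", "R TKA (arthroscopy
repalcement total knee)") are routinely mapped to billing/procedure codes by
text classifiers. A model trained at one institution typically degrades —
often severely — when applied to another institution's notes, because sites
differ both in *which* procedures they perform (label shift) and in *how*
they describe the same procedure (covariate shift: local jargon, acronyms,
misspellings, boilerplate). `genshift` is a toolkit for studying this
degradation and for evaluating cheap, a-priori **divergence statistics** that
predict it before any cross-site evaluation is run.

Because real multi-center registries are not redistributable, the package
includes a first-class synthetic-corpus generator that emulates a
multi-institution procedure registry with controllable label shift,
vocabulary shift and noise — every experiment in the package runs with no
external data.

## What it computes

**Classifier.** Texts are preprocessed at one of three cumulative levels —
*minimal* (lowercasing, punctuation/stop-word removal, 1–10 → words), *spell*
(plus conservative dictionary/edit-distance-1 spell correction), *maximal*
(plus acronym expansion) — then vectorized with TF-IDF and classified by a
feed-forward network (ReLU hidden layers 500/250, softmax output, Adam,
cross-entropy), exposed as the sklearn-style estimator `CptClassifier`.

**Experiment designs.** `run_pairwise` (every institution's model evaluated
on every other institution, self cells by stratified 5-fold CV),
`run_pooled_8020` (one combined model on a stratified 80% of every site),
and `run_loio_holdout` (leave-one-institution-out).

**Divergence statistics.** For institutions A (model source) and B (target):

- directed vocabulary overlap `|V_A ∩ V_B| / |V_B|` and symmetric Jaccard
  similarity `|V_A ∩ V_B| / |V_A ∪ V_B|`;
- label-shift KLD: `KLD_CPT(A→B) = D(P̂_B ‖ P̂_A) = Σ_c p_B(c) ln(p_B(c)/p_A(c))`
  over the shared label set (ε-smoothed, natural log);
- per-label word-distribution KLD (`KLD_word`), measuring how differently the
  two sites describe the *same* procedure;
- composite KLD: `KLD_CPT(A→B) · Σ_c w_c KLD_word_c(A→B)` with label weights
  `w_c ∝ (p_A(c)+p_B(c))/2` (a `weighted_sum` variant is also available).

**Cluster structure.** Institutions are clustered on symmetrized composite
KLD with PAM k-medoids (k chosen by the elbow rule on the within-cluster
sum of squared dissimilarities), embedded in 2-D by classical MDS, and
outlier institutions are flagged by their within-cluster divergence.

## Worked example

```python
import genshift as g

cfg = g.GeneratorConfig(n_institutions=3, n_labels=8,
                        records_per_institution=400, seed=42)
corpus, truth = g.generate_corpus(cfg)
print("example text:", corpus.df["text"].iloc[0])

word_rate, record_rate = g.corpus_misspelling_stats(corpus)
print(f"misspelled words: {100*word_rate:.1f}% | records affected: {100*record_rate:.1f}%")

lex = g.default_lexicons()
m = g.divergence_matrix(corpus, "kld_composite", level="minimal", lexicons=lex)
print(m.values.round(3))

model = g.train(g.Corpus(df=corpus.records_for("inst00").copy(),
                         label_set=corpus.label_set),
                level="minimal", lexicons=lex, random_state=0)
res = g.evaluate(model, g.Corpus(df=corpus.records_for("inst01").copy(),
                                 label_set=corpus.label_set), lexicons=lex)
print(f"inst00 -> inst01: accuracy {res.accuracy:.3f}, micro-F1 {res.micro_f1:.3f}")
```

prints

```
example text: 21,050, reverse replacement of left shoulder, kuto fizofa
misspelled words: 9.8% | records affected: 37.2%
        inst00  inst01  inst02
inst00   0.000   0.881   2.320
inst01   5.544   0.000   4.288
inst02   2.099   2.782   0.000
inst00 -> inst01: accuracy 0.885, micro-F1 0.885
```

The generated note mixes a surgical-code digit group, a laterality token, a
shared phrase and institution-private jargon ("kuto fizofa"). Roughly one
word in ten is misspelled, so about a third of these short records contain at
least one misspelling. The composite-KLD matrix is directed — row A, column
B quantifies applying A's model to B's data — and larger entries predict
worse transfer; here the model still moves across sites well because only
three institutions of moderate divergence are involved. Micro-averaged F1
equals accuracy exactly for single-label multiclass prediction.

A full study (all designs, levels, divergence matrices, correlation,
clustering, report bundle) is one call or one command:

```bash
genshift run --out study_out --seed 1            # full 6x1500 demo study
genshift generate --n-institutions 6 --out corpus.jsonl
genshift divergence --metric kld_composite --in corpus.jsonl --out kld.csv
genshift cluster --distance kld.csv --k auto --out clusters/
```

`study_out/report.txt` summarizes self vs non-self accuracy per level and
design, divergence-performance correlations, the chosen k and flagged
outliers; `results.csv` holds every evaluation cell.

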