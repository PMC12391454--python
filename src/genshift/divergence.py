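"""Dataset-comparison statistics between institutions.

Implements the a-priori transfer heuristics: directed vocabulary overlap,
symmetric Jaccard similarity, KL divergence between label (procedure-code)
distributions (``kld_cpt``), per-label word-distribution KL (``kld_word``),
and a composite scalar combining the two.

Conventions (recorded in matrix metadata):

* KL is computed in natural log (nats) after additive smoothing with
  ``epsilon`` on the union support followed by renormalization.
* ``metric(A -> B)`` quantifies applying an institution-A-trained model to
  institution-B data and is computed as ``D(P_B || P_A)`` — the expected
  extra code length of B's data under A's reference distribution. The
  direction is configurable.
* Composite strategy ``"product"`` (default):
  ``KLD_CPT(A->B) * sum_c w_c KLD_word_c(A->B)`` with label weights
  ``w_c ∝ (p_A(c) + p_B(c)) / 2`` renormalized over the labels observed at
  both institutions; ``"weighted_sum"`` reports the word term alone.
  Labels unobserved at either institution are excluded and counted.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .corpus import Corpus
from .preprocess import Lexicons, PreprocessLevel, Vocabulary, institution_vocabulary, preprocess

__all__ = [
    "DistributionPair",
    "DivergenceMatrix",
    "UndefinedMetricError",
    "vocab_overlap",
    "jaccard",
    "kl_divergence",
    "kld_cpt",
    "kld_word",
    "kld_composite",
    "divergence_matrix",
]

DEFAULT_EPSILON = 1e-9


class UndefinedMetricError(ValueError):
    """Raised when a similarity/divergence is undefined for the inputs."""


@dataclass(frozen=True)
class DistributionPair:
    """Two smoothed probability vectors on a common ordered support."""

    support: tuple[str, ...]
    p: np.ndarray
    q: np.ndarray
    smoothing_epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if len(self.p) != len(self.support) or len(self.q) != len(self.support):
            raise ValueError("p/q length must match support")
        for name, v in (("p", self.p), ("q", self.q)):
            if abs(float(np.sum(v)) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {np.sum(v)!r})")
            if (v <= 0).any():
                raise ValueError(f"{name} must be strictly positive after smoothing")

    @classmethod
    def from_counts(cls, support: Sequence[str],
                    counts_p: Mapping[str, float] | Sequence[float] | np.ndarray,
                    counts_q: Mapping[str, float] | Sequence[float] | np.ndarray,
                    smoothing_epsilon: float = DEFAULT_EPSILON,
                    ) -> "DistributionPair":
        """Build from (possibly zero-containing) counts or weights: add
        ``epsilon`` on the union support and renormalize."""
        support = tuple(support)
        if not support:
            raise UndefinedMetricError("empty support")

        def vec(counts) -> np.ndarray:
            if isinstance(counts, Mapping):
                v = np.array([float(counts.get(s, 0.0)) for s in support])
            else:
                v = np.asarray(counts, dtype=float)
            if (v < 0).any():
                raise ValueError("negative counts")
            if v.sum() == 0:
                raise UndefinedMetricError("all-zero counts")
            v = v + smoothing_epsilon
            return v / v.sum()

        return cls(support=support, p=vec(counts_p), q=vec(counts_q),
                   smoothing_epsilon=smoothing_epsilon)


def kl_divergence(pair: DistributionPair) -> float:
    """``sum_i p_i ln(p_i / q_i)`` in nats; >= 0, 0 iff p == q."""
    return float(np.sum(rel_entr(pair.p, pair.q)))


# ---------------------------------------------------------------------------
# vocabulary set metrics


def _tokens(vocab: Vocabulary | frozenset[str] | set[str]) -> frozenset[str]:
    return vocab.tokens if isinstance(vocab, Vocabulary) else frozenset(vocab)


def vocab_overlap(vocab_a, vocab_b) -> float:
    """Directed overlap |A ∩ B| / |B|: how much of B's vocabulary an
    A-trained model has seen."""
    a, b = _tokens(vocab_a), _tokens(vocab_b)
    if not b:
        raise UndefinedMetricError("overlap undefined for empty B vocabulary")
    return len(a & b) / len(b)


def jaccard(vocab_a, vocab_b) -> float:
    """Symmetric Jaccard similarity |A ∩ B| / |A ∪ B|."""
    a, b = _tokens(vocab_a), _tokens(vocab_b)
    if not a and not b:
        raise UndefinedMetricError("jaccard undefined for two empty vocabularies")
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# corpus-level KLD metrics


def _directed(counts_a, counts_b, support, epsilon: float, direction: str) -> float:
    """metric(A->B). direction 'b_given_a' => D(P_B || P_A) (default)."""
    if direction == "b_given_a":
        pair = DistributionPair.from_counts(support, counts_b, counts_a, epsilon)
    elif direction == "a_given_b":
        pair = DistributionPair.from_counts(support, counts_a, counts_b, epsilon)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return kl_divergence(pair)


def kld_cpt(corpus: Corpus, inst_a: str, inst_b: str,
            epsilon: float = DEFAULT_EPSILON,
            direction: str = "b_given_a") -> float:
    """Label-shift KLD between two institutions on the global label set."""
    ca = corpus.records_for(inst_a)["label"].value_counts().to_dict()
    cb = corpus.records_for(inst_b)["label"].value_counts().to_dict()
    return _directed(ca, cb, corpus.label_set, epsilon, direction)


def _word_counts(corpus: Corpus, inst: str, label: str,
                 level: PreprocessLevel | str, lexicons: Lexicons) -> Counter:
    sub = corpus.records_for(inst)
    sub = sub[sub["label"] == label]
    counts: Counter = Counter()
    for text in sub["text"]:
        counts.update(preprocess(text, level, lexicons))
    return counts


def kld_word(corpus: Corpus, inst_a: str, inst_b: str, label: str,
             level: PreprocessLevel | str, lexicons: Lexicons,
             epsilon: float = DEFAULT_EPSILON,
             direction: str = "b_given_a") -> float:
    """Covariate-shift KLD between word distributions within one label.

    Raises :class:`UndefinedMetricError` when the label is unobserved at
    either institution (callers exclude and count such labels).
    """
    ca = _word_counts(corpus, inst_a, label, level, lexicons)
    cb = _word_counts(corpus, inst_b, label, level, lexicons)
    if not ca or not cb:
        raise UndefinedMetricError(
            f"label {label!r} unobserved at one institution")
    support = sorted(set(ca) | set(cb))
    return _directed(ca, cb, support, epsilon, direction)


def kld_composite(corpus: Corpus, inst_a: str, inst_b: str,
                  level: PreprocessLevel | str, lexicons: Lexicons,
                  epsilon: float = DEFAULT_EPSILON,
                  strategy: str = "product",
                  direction: str = "b_given_a",
                  return_detail: bool = False):
    """Composite divergence combining label shift and per-label word shift."""
    if strategy not in ("product", "weighted_sum"):
        raise ValueError(f"unknown composite strategy {strategy!r}")
    pa = corpus.label_distribution(inst_a)
    pb = corpus.label_distribution(inst_b)
    word_terms: dict[str, float] = {}
    weights: dict[str, float] = {}
    n_skipped = 0
    for label in corpus.label_set:
        try:
            w = kld_word(corpus, inst_a, inst_b, label, level, lexicons,
                         epsilon, direction)
        except UndefinedMetricError:
            n_skipped += 1
            continue
        word_terms[label] = w
        weights[label] = (float(pa[label]) + float(pb[label])) / 2.0
    if not word_terms:
        raise UndefinedMetricError("no label is observed at both institutions")
    total_w = sum(weights.values())
    word_part = sum(weights[c] / total_w * word_terms[c] for c in word_terms)
    cpt_part = kld_cpt(corpus, inst_a, inst_b, epsilon, direction)
    value = cpt_part * word_part if strategy == "product" else word_part
    if return_detail:
        return value, {"kld_cpt": cpt_part, "word_part": word_part,
                       "n_labels_skipped": n_skipped,
                       "strategy": strategy, "direction": direction}
    return value


# ---------------------------------------------------------------------------
# matrices


@dataclass
class DivergenceMatrix:
    """Institution × institution matrix of one metric, with provenance."""

    metric_name: str
    values: pd.DataFrame  # index = "from" (A), columns = "to" (B)
    directed: bool
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.values.columns):
            raise ValueError("matrix must have identical row/column institutions")
        diag = np.diag(self.values.to_numpy())
        expected = 1.0 if self.metric_name in ("overlap", "jaccard") else 0.0
        if not np.allclose(diag, expected, atol=1e-9):
            raise ValueError(f"{self.metric_name} matrix diagonal must be {expected}")
        if self.metric_name.startswith("kld"):
            arr = self.values.to_numpy()
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError("KLD matrix must be finite and non-negative")

    @property
    def institutions(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def symmetrized(self) -> pd.DataFrame:
        """Element-wise mean of M and M^T (dissimilarity for clustering)."""
        m = self.values.to_numpy()
        sym = (m + m.T) / 2.0
        np.fill_diagonal(sym, np.diag(m))
        return pd.DataFrame(sym, index=self.values.index, columns=self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path, metric_name: str = "unknown",
                 directed: bool = True) -> "DivergenceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(metric_name=metric_name, values=df, directed=directed)


def divergence_matrix(corpus: Corpus, metric: str,
                      level: PreprocessLevel | str = PreprocessLevel.MINIMAL,
                      lexicons: Lexicons | None = None,
                      epsilon: float = DEFAULT_EPSILON,
                      strategy: str = "product",
                      direction: str = "b_given_a") -> DivergenceMatrix:
    """Compute a full pairwise matrix of one metric over all institutions."""
    from .preprocess import default_lexicons

    if lexicons is None:
        lexicons = default_lexicons()
    insts = corpus.institutions
    n = len(insts)
    values = np.zeros((n, n))
    vocabs = None
    if metric in ("overlap", "jaccard"):
        vocabs = {i: institution_vocabulary(corpus, i, level, lexicons)
                  for i in insts}
    for i, a in enumerate(insts):
        for j, b in enumerate(insts):
            if metric == "overlap":
                values[i, j] = vocab_overlap(vocabs[a], vocabs[b])
            elif metric == "jaccard":
                values[i, j] = jaccard(vocabs[a], vocabs[b])
            elif metric == "kld_cpt":
                values[i, j] = 0.0 if i == j else kld_cpt(
                    corpus, a, b, epsilon, direction)
            elif metric == "kld_composite":
                values[i, j] = 0.0 if i == j else kld_composite(
                    corpus, a, b, level, lexicons, epsilon, strategy, direction)
            else:
                raise ValueError(f"unknown metric {metric!r}")
    meta = {"metric": metric, "level": str(PreprocessLevel.parse(level).value),
            "epsilon": epsilon, "log_base": "e", "direction": direction}
    if metric == "kld_composite":
        meta["strategy"] = strategy
    return DivergenceMatrix(
        metric_name=metric,
        values=pd.DataFrame(values, index=list(insts), columns=list(insts)),
        directed=(metric != "jaccard"),
        metadata=meta)
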