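"""TF-IDF + feed-forward network procedure-code classifier.

The reference architecture: preprocessed text vectorized by a TF-IDF matrix
feeding a three-layer network — two ReLU hidden layers of 500 and 250 units
and a softmax output over the shared label set — trained with Adam under
cross-entropy loss. Here the network is sklearn's ``MLPClassifier``;
regularization is an L2 penalty (``alpha``) rather than dropout, which the
sklearn backend does not provide.

TF-IDF dialect (recorded in model metadata): sklearn's smoothed idf,
``idf(t) = ln((1 + n) / (1 + df(t))) + 1``, raw term counts, L2-normalized
rows. The vocabulary is fit on training documents only; unseen test tokens
are ignored.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import accuracy_score, f1_score
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .corpus import Corpus
from .preprocess import Lexicons, PreprocessLevel, TextPreprocessor, default_lexicons

__all__ = [
    "CptClassifier",
    "EvalResult",
    "fit_tfidf",
    "train",
    "evaluate",
    "DegenerateTrainingError",
]

TFIDF_DIALECT = "sklearn smooth_idf: ln((1+n)/(1+df))+1, raw tf, l2 norm"


class DegenerateTrainingError(ValueError):
    """Raised when the training subset cannot support classification."""


@dataclass(frozen=True)
class EvalResult:
    """One cell of the pairwise evaluation matrix.

    For single-label multiclass prediction micro-averaged F1 equals accuracy
    (pooled FP == pooled FN); the identity is asserted at construction.
    """

    train_id: str
    test_id: str
    level: str
    accuracy: float
    micro_f1: float
    n_test: int

    def __post_init__(self) -> None:
        if abs(self.accuracy - self.micro_f1) > 1e-12:
            raise ValueError(
                f"micro-F1 ({self.micro_f1}) must equal accuracy "
                f"({self.accuracy}) for single-label multiclass evaluation")


def fit_tfidf(token_sequences) -> TfidfVectorizer:
    """Fit the TF-IDF model on whitespace-joined token strings."""
    docs = [s if isinstance(s, str) else " ".join(s) for s in token_sequences]
    if not any(d.strip() for d in docs):
        raise ValueError("cannot fit TF-IDF on all-empty documents")
    vec = TfidfVectorizer(tokenizer=str.split, preprocessor=None,
                          token_pattern=None, lowercase=False)
    vec.fit(docs)
    return vec


class CptClassifier(ClassifierMixin, BaseEstimator):
    """TF-IDF + MLP classifier over preprocessed token strings.

    Parameters
    ----------
    hidden_layer_sizes : widths of the ReLU hidden layers.
    alpha : L2 penalty (regularizer standing in for the reference
        architecture's dropout).
    learning_rate, batch_size, max_epochs : Adam settings; training stops
        early when the loss plateaus (``n_iter_no_change`` epochs within
        ``tol``).
    random_state : seeds weight init and batch shuffling; fitting is
        deterministic given the seed.
    """

    def __init__(self, hidden_layer_sizes=(500, 250), alpha: float = 1e-4,
                 learning_rate: float = 1e-3, batch_size: int = 128,
                 max_epochs: int = 30, n_iter_no_change: int = 3,
                 tol: float = 1e-3, random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.n_iter_no_change = n_iter_no_change
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y) -> "CptClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DegenerateTrainingError(
                "training subset must contain at least 2 distinct labels")
        self.vectorizer_ = fit_tfidf(X)
        docs = [s if isinstance(s, str) else " ".join(s) for s in X]
        Xt = self.vectorizer_.transform(docs)
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu", solver="adam", alpha=self.alpha,
            batch_size=min(self.batch_size, Xt.shape[0]),
            learning_rate_init=self.learning_rate,
            max_iter=self.max_epochs, shuffle=True,
            n_iter_no_change=self.n_iter_no_change, tol=self.tol,
            random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp_.fit(Xt, y)
        self.classes_ = self.mlp_.classes_
        self.metadata_ = {"tfidf_dialect": TFIDF_DIALECT,
                          "n_features": int(Xt.shape[1]),
                          "params": self.get_params()}
        return self

    def _vectorize(self, X):
        docs = [s if isinstance(s, str) else " ".join(s) for s in X]
        return self.vectorizer_.transform(docs)

    def predict(self, X):
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict(self._vectorize(X))

    def predict_proba(self, X):
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict_proba(self._vectorize(X))


@dataclass
class TrainedModel:
    """A fitted classifier plus the provenance needed for leakage audits."""

    estimator: CptClassifier
    train_id: str
    level: str
    train_fingerprint: str
    train_indices: tuple[int, ...]


def train(corpus_subset: Corpus, level: PreprocessLevel | str = "minimal",
          lexicons: Lexicons | None = None, train_id: str | None = None,
          **clf_params) -> TrainedModel:
    """Preprocess an institution subset at ``level`` and fit the classifier."""
    lexicons = lexicons if lexicons is not None else default_lexicons()
    level = PreprocessLevel.parse(level)
    pre = TextPreprocessor(level=level, lexicons=lexicons).fit([])
    docs = pre.transform(corpus_subset.df["text"].tolist())
    est = CptClassifier(**clf_params)
    est.fit(docs, corpus_subset.df["label"].to_numpy())
    return TrainedModel(
        estimator=est,
        train_id=train_id or "+".join(corpus_subset.institutions),
        level=level.value,
        train_fingerprint=corpus_subset.fingerprint(),
        train_indices=tuple(corpus_subset.df.index))


def evaluate(model: TrainedModel | CptClassifier, test_subset: Corpus,
             level: PreprocessLevel | str | None = None,
             lexicons: Lexicons | None = None,
             test_id: str | None = None) -> EvalResult:
    """Evaluate on a test subset: accuracy and micro-averaged F1."""
    if len(test_subset) == 0:
        raise ValueError("empty test subset")
    if isinstance(model, TrainedModel):
        est = model.estimator
        level = level if level is not None else model.level
        train_id = model.train_id
    else:
        est = model
        train_id = "model"
        if level is None:
            raise ValueError("level required for a bare estimator")
    lexicons = lexicons if lexicons is not None else default_lexicons()
    pre = TextPreprocessor(level=level, lexicons=lexicons).fit([])
    docs = pre.transform(test_subset.df["text"].tolist())
    y_true = test_subset.df["label"].to_numpy()
    y_pred = est.predict(docs)
    acc = float(accuracy_score(y_true, y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = float(f1_score(y_true, y_pred, average="micro"))
    return EvalResult(
        train_id=train_id,
        test_id=test_id or "+".join(test_subset.institutions),
        level=str(PreprocessLevel.parse(level).value),
        accuracy=acc, micro_f1=f1, n_test=len(test_subset))
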