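"""Divergence metrics: closed forms, hand oracles, and set-theoretic laws."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genshift as g
from genshift.corpus import Corpus
from genshift.divergence import (DEFAULT_EPSILON, DistributionPair,
                                 DivergenceMatrix, UndefinedMetricError,
                                 divergence_matrix, jaccard, kl_divergence,
                                 kld_composite, kld_cpt, kld_word,
                                 vocab_overlap)


def hand_kl(counts_p, counts_q, eps=DEFAULT_EPSILON):
    """Independent evaluation of smoothed KL from raw counts."""
    p = [c + eps for c in counts_p]
    q = [c + eps for c in counts_q]
    sp, sq = sum(p), sum(q)
    return sum((pi / sp) * math.log((pi / sp) / (qi / sq))
               for pi, qi in zip(p, q))


# ---------------------------------------------------------------------------
# set metrics


def test_overlap_hand_enumeration():
    a, b = {"a", "b", "c"}, {"b", "c", "d", "e"}
    assert vocab_overlap(a, b) == 0.5          # |{b,c}| / |B|=4
    assert vocab_overlap(b, a) == pytest.approx(2 / 3)
    assert vocab_overlap(a, a) == 1.0
    assert vocab_overlap({"x"}, {"y", "z"}) == 0.0
    with pytest.raises(UndefinedMetricError):
        vocab_overlap(a, set())


def test_jaccard_hand_enumeration():
    a, b = {"a", "b", "c"}, {"b", "c", "d", "e"}
    # |A ∩ B| = |{b,c}| = 2, |A ∪ B| = |{a,b,c,d,e}| = 5
    assert jaccard(a, b) == pytest.approx(2 / 5)
    assert jaccard(b, a) == jaccard(a, b)
    assert jaccard(a, a) == 1.0
    assert jaccard({"x"}, {"y"}) == 0.0
    with pytest.raises(UndefinedMetricError):
        jaccard(set(), set())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
def test_jaccard_bounded_by_directed_overlaps(a, b):
    if not a or not b:
        return
    j = jaccard(a, b)
    assert j <= min(vocab_overlap(a, b), vocab_overlap(b, a)) + 1e-12


# ---------------------------------------------------------------------------
# KL divergence


def test_kl_identical_distributions_is_zero():
    pair = DistributionPair.from_counts(["a", "b"], [0.5, 0.5], [0.5, 0.5])
    assert kl_divergence(pair) == pytest.approx(0.0, abs=1e-9)


def test_kl_closed_form_anchor():
    # 0.5 ln 2 + 0.5 ln(2/3) = 0.1438 nats
    pair = DistributionPair.from_counts(["a", "b"], [0.5, 0.5], [0.25, 0.75])
    assert kl_divergence(pair) == pytest.approx(0.14384103622589046, abs=1e-4)


def test_kl_with_zero_mass_smoothing():
    pair = DistributionPair.from_counts(["a", "b"], [1, 0], [0.5, 0.5])
    assert kl_divergence(pair) == pytest.approx(math.log(2), abs=1e-3)


def test_distribution_pair_validates_normalization():
    with pytest.raises(ValueError):
        DistributionPair(support=("a", "b"), p=np.array([0.7, 0.7]),
                         q=np.array([0.5, 0.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=2, max_size=8),
       st.lists(st.integers(0, 50), min_size=2, max_size=8))
def test_kl_nonnegative_and_zero_iff_equal(cp, cq):
    n = min(len(cp), len(cq))
    cp, cq = cp[:n], cq[:n]
    if sum(cp) == 0 or sum(cq) == 0:
        return
    support = [str(i) for i in range(n)]
    pair = DistributionPair.from_counts(support, cp, cq)
    d = kl_divergence(pair)
    assert d >= -1e-12
    sp, sq = sum(cp), sum(cq)
    if all(a * sq == b * sp for a, b in zip(cp, cq)):
        assert d == pytest.approx(0.0, abs=1e-9)
    elif d < 1e-9:  # KL ~ 0 must imply proportional counts
        raise AssertionError("zero divergence for unequal distributions")


# ---------------------------------------------------------------------------
# corpus-level metrics


def _two_institution_corpus():
    rows = [
        ("A", "left knee", "L1"),
        ("A", "right knee", "L1"),
        ("A", "hip replacement", "L2"),
        ("B", "left knee", "L1"),
        ("B", "hip revision", "L2"),
        ("B", "hip replacement", "L2"),
    ]
    return Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                  label_set=("L1", "L2"))


def test_kld_cpt_closed_form():
    rows = ([("A", "t", "L1")] * 9 + [("A", "t", "L2")] * 1
            + [("B", "t", "L1")] * 1 + [("B", "t", "L2")] * 9)
    corpus = Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                    label_set=("L1", "L2"))
    # D(P_B || P_A) = 0.1 ln(0.1/0.9) + 0.9 ln(0.9/0.1) = 0.8 ln 9
    assert kld_cpt(corpus, "A", "B") == pytest.approx(0.8 * math.log(9), abs=1e-3)
    assert kld_cpt(corpus, "A", "A") == pytest.approx(0.0, abs=1e-9)


def test_kld_cpt_parameter_recovery_against_ground_truth():
    cfg = g.GeneratorConfig(n_institutions=2, n_labels=16,
                            records_per_institution=5000, seed=21)
    corpus, truth = g.generate_corpus(cfg)
    est = kld_cpt(corpus, "inst00", "inst01")
    analytic = truth.analytic_label_kld("inst00", "inst01")
    assert est == pytest.approx(analytic, abs=0.05)


def test_kld_word_hand_oracle(lexicons):
    corpus = _two_institution_corpus()
    # L1 at A: texts "left knee"/"right knee" -> counts over (knee,left,right)
    got = kld_word(corpus, "A", "B", "L1", "minimal", lexicons)
    expected = hand_kl([1, 1, 0], [2, 1, 1])  # D(B||A): p=B counts, q=A counts
    assert got == pytest.approx(expected, abs=1e-9)
    assert kld_word(corpus, "A", "A", "L1", "minimal", lexicons) == \
        pytest.approx(0.0, abs=1e-9)


def test_kld_word_single_record_symmetric_construction(lexicons):
    rows = [("A", "left knee", "L"), ("B", "right knee", "L")]
    corpus = Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                    label_set=("L",))
    ab = kld_word(corpus, "A", "B", "L", "minimal", lexicons)
    ba = kld_word(corpus, "B", "A", "L", "minimal", lexicons)
    assert ab > 0 and math.isfinite(ab)
    assert ab == pytest.approx(ba, rel=1e-9)  # construction is symmetric


def test_kld_word_incomparable_label(lexicons):
    rows = [("A", "left knee", "L1"), ("B", "hip", "L2")]
    corpus = Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                    label_set=("L1", "L2"))
    with pytest.raises(UndefinedMetricError):
        kld_word(corpus, "A", "B", "L1", "minimal", lexicons)


def test_composite_hand_oracle(lexicons):
    corpus = _two_institution_corpus()
    # word terms D(B||A) per label over minimal-token union supports
    w_l1 = hand_kl([1, 1, 0], [2, 1, 1])            # (knee,left,right)
    w_l2 = hand_kl([2, 1, 1], [1, 1, 0])            # (hip,replacement,revision)
    cpt = hand_kl([1, 2], [2, 1])                    # label counts B vs A
    # weights (p_A + p_B)/2 per label, renormalized: both 1/2 here
    word_part = 0.5 * w_l1 + 0.5 * w_l2
    got_prod = kld_composite(corpus, "A", "B", "minimal", lexicons)
    got_sum = kld_composite(corpus, "A", "B", "minimal", lexicons,
                            strategy="weighted_sum")
    assert got_prod == pytest.approx(cpt * word_part, abs=1e-9)
    assert got_sum == pytest.approx(word_part, abs=1e-9)


def test_composite_zero_for_identical_corpora(lexicons):
    rows = [("A", "left knee", "L1"), ("A", "hip replacement", "L2"),
            ("B", "left knee", "L1"), ("B", "hip replacement", "L2")]
    corpus = Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                    label_set=("L1", "L2"))
    for strategy in ("product", "weighted_sum"):
        assert kld_composite(corpus, "A", "B", "minimal", lexicons,
                             strategy=strategy) == pytest.approx(0.0, abs=1e-6)


def test_composite_separability_label_mix_only(lexicons):
    # identical per-label texts, different label mixes -> word terms ~0 so
    # the product collapses to ~0
    rows = ([("A", "left knee", "L1")] * 3 + [("A", "hip replacement", "L2")]
            + [("B", "left knee", "L1")] + [("B", "hip replacement", "L2")] * 3)
    corpus = Corpus(df=pd.DataFrame(rows, columns=["institution_id", "text", "label"]),
                    label_set=("L1", "L2"))
    assert kld_composite(corpus, "A", "B", "minimal", lexicons) == \
        pytest.approx(0.0, abs=1e-6)
    assert kld_cpt(corpus, "A", "B") > 0.1


# ---------------------------------------------------------------------------
# matrices


def test_divergence_matrices_invariants(lexicons, small_corpus):
    corpus, _ = small_corpus
    mats = {m: divergence_matrix(corpus, m, "minimal", lexicons)
            for m in ("overlap", "jaccard", "kld_cpt", "kld_composite")}
    n = len(corpus.institutions)
    for name, m in mats.items():
        arr = m.values.to_numpy()
        assert arr.shape == (n, n)
        expected_diag = 1.0 if name in ("overlap", "jaccard") else 0.0
        np.testing.assert_allclose(np.diag(arr), expected_diag, atol=1e-9)
        if name.startswith("kld"):
            assert (arr >= 0).all() and np.isfinite(arr).all()
    # jaccard symmetric; overlap generally not (witness)
    jac = mats["jaccard"].values.to_numpy()
    np.testing.assert_allclose(jac, jac.T, atol=1e-12)
    ov = mats["overlap"].values.to_numpy()
    assert not np.allclose(ov, ov.T)


def test_matrix_diagonal_validation():
    bad = pd.DataFrame([[1.0, 0.2], [0.3, 0.0]], index=["A", "B"],
                       columns=["A", "B"])
    with pytest.raises(ValueError):
        DivergenceMatrix(metric_name="kld_cpt", values=bad, directed=True)


def test_matrix_csv_round_trip(tmp_path, lexicons, small_corpus):
    corpus, _ = small_corpus
    m = divergence_matrix(corpus, "kld_composite", "minimal", lexicons)
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = DivergenceMatrix.from_csv(path, metric_name="kld_composite")
    np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy(),
                               rtol=1e-9)


def test_composite_monotone_in_private_vocab_fraction(lexicons):
    """Mean composite KLD is non-decreasing along a pvf sweep (5 seeds)."""
    means = []
    for pvf in (0.1, 0.4, 0.8):
        vals = []
        for seed in range(5):
            cfg = g.GeneratorConfig(n_institutions=3, n_labels=6,
                                    records_per_institution=200,
                                    private_vocab_fraction=pvf, seed=seed)
            corpus, _ = g.generate_corpus(cfg)
            m = divergence_matrix(corpus, "kld_composite", "minimal", lexicons)
            arr = m.values.to_numpy()
            vals.append(arr[~np.eye(len(arr), dtype=bool)].mean())
        means.append(np.mean(vals))
    assert means[0] <= means[1] <= means[2]
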