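"""Aggregation rules: simple, domain-weighted and PCA scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import eig as general_eig

import facility_readiness as fr
from facility_readiness.core import MatrixPurpose
from facility_readiness.errors import (DegenerateItemError,
                                       InsufficientDataError, RescaleError,
                                       UndefinedScoreError)

from conftest import make_matrix

# ---------------------------------------------------------------- simple

def test_simple_score_is_fraction_of_available_items():
    mx = make_matrix([[1, 1, 0, 1]])
    (s,) = fr.score_simple(mx)
    assert s.score == 0.75 and s.n_applicable == 4


def test_simple_score_ceiling_and_floor():
    mx = make_matrix([[1, 1, 1, 1], [0, 0, 0, 0]])
    hi, lo = fr.score_simple(mx)
    assert hi.score == 1.0 and lo.score == 0.0


def test_not_applicable_item_shrinks_the_denominator():
    app = [[True, False, True, True]]
    mx = make_matrix([[1, 0, 0, 1]], applicable=app)
    (s,) = fr.score_simple(mx)
    assert s.score == pytest.approx(2 / 3, abs=0) and s.n_applicable == 3


def test_facility_with_no_applicable_items_is_an_error():
    mx = make_matrix([[0, 0]], applicable=[[False, False]])
    with pytest.raises(UndefinedScoreError, match="f0"):
        fr.score_simple(mx)


# -------------------------------------------------------------- weighted

def test_weighted_score_averages_domain_fractions():
    mx = make_matrix([[1, 0, 1, 1, 1]])
    partition = {"A": ["i0", "i1"], "B": ["i2", "i3", "i4"]}
    (s,) = fr.score_domain_weighted(mx, partition)
    assert s.score == (0.5 + 1.0) / 2
    assert s.domain_scores == {"A": 0.5, "B": 1.0}


def test_fully_not_applicable_domain_is_dropped_from_the_mean():
    app = [[False, False, True, True]]
    mx = make_matrix([[0, 0, 1, 0]], applicable=app)
    partition = {"A": ["i0", "i1"], "B": ["i2", "i3"]}
    (s,) = fr.score_domain_weighted(mx, partition)
    assert s.score == 0.5
    assert "A" not in s.domain_scores


def test_excluded_domain_reported_but_not_averaged():
    mx = make_matrix([[0, 0, 1, 1]])
    partition = {"A": ["i0", "i1"], "B": ["i2", "i3"]}
    (s,) = fr.score_domain_weighted(mx, partition, excluded_domains={"A"})
    assert s.score == 1.0
    assert s.domain_scores["A"] == 0.0  # still deconstructable


def test_all_domains_excluded_is_an_error():
    mx = make_matrix([[1, 0]])
    with pytest.raises(UndefinedScoreError):
        fr.score_domain_weighted(mx, {"A": ["i0", "i1"]}, excluded_domains={"A"})


@settings(max_examples=40, derandomize=True)
@given(arrays(np.int8, (5, 4), elements=st.integers(0, 1)))
def test_single_domain_weighted_equals_simple_exactly(values):
    mx = make_matrix(values)
    simple = fr.score_simple(mx)
    weighted = fr.score_domain_weighted(mx, {"only": mx.item_ids})
    for s, w in zip(simple, weighted):
        assert w.score == s.score  # exact rational arithmetic both ways


@settings(max_examples=40, derandomize=True)
@given(arrays(np.int8, (6, 5), elements=st.integers(0, 1)),
       st.integers(0, 5), st.integers(0, 4))
def test_flipping_an_item_to_available_never_lowers_additive_scores(values, i, j):
    if values[i, j] == 1:
        values = values.copy()
        values[i, j] = 0
    flipped = values.copy()
    flipped[i, j] = 1
    partition = {"A": ["i0", "i1"], "B": ["i2", "i3", "i4"]}
    for scorer in (fr.score_simple,
                   lambda m: fr.score_domain_weighted(m, partition)):
        before = scorer(make_matrix(values))[i].score
        after = scorer(make_matrix(flipped))[i].score
        assert after >= before


def test_additive_scores_invariant_to_item_and_facility_order():
    rng = np.random.default_rng(3)
    values = rng.integers(0, 2, size=(8, 6)).astype(np.int8)
    mx = make_matrix(values)
    perm_f, perm_i = rng.permutation(8), rng.permutation(6)
    shuffled = make_matrix(values[np.ix_(perm_f, perm_i)],
                           facility_ids=[mx.facility_ids[i] for i in perm_f],
                           item_ids=[mx.item_ids[j] for j in perm_i])
    base = {s.facility_id: s.score for s in fr.score_simple(mx)}
    shuf = {s.facility_id: s.score for s in fr.score_simple(shuffled)}
    assert base == shuf


# ------------------------------------------------------------------- PCA

def _pca_fixture():
    rng = np.random.default_rng(11)
    theta = rng.normal(0, 1, 40)
    probs = 1 / (1 + np.exp(-(theta[:, None] - np.array([-0.5, 0.0, 0.4, 0.8]))))
    values = (rng.random((40, 4)) < probs).astype(np.int8)
    return make_matrix(values, purpose=MatrixPurpose.PCA)


def _loop_correlation(X):
    """Correlation matrix from the explicit covariance formula."""
    n, p = X.shape
    R = np.empty((p, p))
    for a in range(p):
        for b in range(p):
            xa, xb = X[:, a], X[:, b]
            cov = sum((xa[i] - xa.mean()) * (xb[i] - xb.mean()) for i in range(n)) / n
            va = sum((v - xa.mean()) ** 2 for v in xa) / n
            vb = sum((v - xb.mean()) ** 2 for v in xb) / n
            R[a, b] = cov / math.sqrt(va * vb)
    return R


def test_eigenpairs_match_independent_general_eigensolver():
    mx = _pca_fixture()
    model = fr.fit_pca(mx)
    R = _loop_correlation(mx.values.astype(float))
    w, V = general_eig(R)  # nonsymmetric QR route, independent of eigh
    w = np.real(w)
    order = np.argsort(w)[::-1]
    assert np.allclose(model.eigenvalues, w[order], atol=1e-8)
    v1 = np.real(V[:, order[0]])
    if v1.sum() < 0:
        v1 = -v1
    assert np.allclose(np.abs(model.loadings), np.abs(v1), atol=1e-8)


def test_eigenvalue_sum_equals_item_count():
    mx = _pca_fixture()
    model = fr.fit_pca(mx)
    assert model.eigenvalues.sum() == pytest.approx(len(mx.item_ids), abs=1e-10)
    assert model.variance_explained_first == pytest.approx(
        model.eigenvalues[0] / len(mx.item_ids), abs=1e-12)


def test_duplicated_items_load_equally_on_the_first_component():
    rng = np.random.default_rng(5)
    col = rng.integers(0, 2, size=12).astype(np.int8)
    noise = rng.integers(0, 2, size=12).astype(np.int8)
    values = np.column_stack([col, col, noise])
    model = fr.fit_pca(make_matrix(values, purpose=MatrixPurpose.PCA))
    assert model.loadings[0] == pytest.approx(model.loadings[1], abs=1e-10)


def test_pca_scores_order_matches_oracle_projection():
    mx = _pca_fixture()
    model = fr.fit_pca(mx)
    scores = fr.score_pca(mx, model)
    X = mx.values.astype(float)
    R = _loop_correlation(X)
    w, V = general_eig(R)
    v1 = np.real(V[:, np.argmax(np.real(w))])
    if v1.sum() < 0:
        v1 = -v1
    raw = ((X - X.mean(0)) / X.std(0, ddof=1)) @ v1
    assert (np.argsort([s.score for s in scores]) == np.argsort(raw)).all()


def test_pca_rescaling_endpoints_are_exactly_zero_and_one():
    mx = _pca_fixture()
    model = fr.fit_pca(mx)
    vals = np.array([s.score for s in fr.score_pca(mx, model)])
    assert vals.min() == 0.0 and vals.max() == 1.0
    assert ((vals >= 0) & (vals <= 1)).all()


def test_pca_scores_invariant_to_item_order():
    mx = _pca_fixture()
    base = np.array([s.score for s in fr.score_pca(mx, fr.fit_pca(mx))])
    perm = np.random.default_rng(0).permutation(len(mx.item_ids))
    shuffled = make_matrix(mx.values[:, perm], purpose=MatrixPurpose.PCA,
                           item_ids=[mx.item_ids[j] for j in perm])
    other = np.array([s.score for s in fr.score_pca(shuffled, fr.fit_pca(shuffled))])
    assert np.allclose(base, other, atol=1e-9)


def test_zero_variance_item_refused_then_droppable():
    values = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]], dtype=np.int8)
    mx = make_matrix(values, purpose=MatrixPurpose.PCA)
    with pytest.raises(DegenerateItemError) as exc:
        fr.fit_pca(mx)
    assert exc.value.item_ids == ["i0"]
    with pytest.warns(UserWarning, match="i0"):
        model = fr.fit_pca(mx, on_degenerate="drop")
    assert model.item_ids == ["i1", "i2"]
    assert len(fr.score_pca(mx, model)) == 4


def test_identical_facilities_cannot_be_rescaled():
    values = np.array([[1, 0], [1, 0], [1, 0]], dtype=np.int8)
    mx = make_matrix(values, purpose=MatrixPurpose.PCA)
    with pytest.raises((RescaleError, DegenerateItemError)):
        model = fr.fit_pca(mx)
        fr.score_pca(mx, model)


def test_single_facility_is_insufficient_for_pca():
    mx = make_matrix(np.array([[1, 0]], dtype=np.int8), purpose=MatrixPurpose.PCA)
    with pytest.raises(InsufficientDataError):
        fr.fit_pca(mx)


def test_flipping_item_with_positive_loading_never_lowers_pca_score():
    mx = _pca_fixture()
    model = fr.fit_pca(mx)
    j = int(np.argmax(model.loadings))
    assert model.loadings[j] > 0
    values = mx.values.copy()
    i = int(np.flatnonzero(values[:, j] == 0)[0])
    flipped = values.copy()
    flipped[i, j] = 1
    raw_before = ((values.astype(float) - model.item_means) / model.item_sds) @ model.loadings
    raw_after = ((flipped.astype(float) - model.item_means) / model.item_sds) @ model.loadings
    assert raw_after[i] >= raw_before[i]
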