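import itertools
from datetime import datetime, timezone

import numpy as np
import pytest

from sparsetopics.errors import NoSignalError, RowRemovalError
from sparsetopics.preprocess import Document
from sparsetopics.spca import (
    SpcaConfig,
    TopicModel,
    associate_docs,
    fit_topic_model,
    remove_docs,
    sparse_rank1,
)
from sparsetopics.term_matrix import build_matrix, build_vocabulary

TS = datetime(2012, 2, 1, tzinfo=timezone.utc)


def _doc(tokens, doc_id, multiplicity=1):
    return Document(
        doc_id=doc_id,
        tokens=tuple(tokens),
        multiplicity=multiplicity,
        source_ids=tuple(f"{doc_id}.{i}" for i in range(multiplicity)),
        timestamp=TS,
    )


def _tdm(token_lists):
    docs = [_doc(toks, f"d{i}") for i, toks in enumerate(token_lists)]
    vocab = build_vocabulary(docs, min_df=1, max_df_frac=1.0)
    return build_matrix(docs, vocab)


def brute_force_sparse_sv(X, k):
    """Exhaustive support enumeration: best sigma and all optimal supports."""
    n_cols = X.shape[1]
    best, supports = -1.0, []
    for S in itertools.combinations(range(n_cols), k):
        sigma = np.linalg.svd(X[:, S], compute_uv=False)[0]
        if sigma > best + 1e-9:
            best, supports = sigma, [S]
        elif sigma >= best - 1e-9:
            supports.append(S)
    return best, supports


class TestSparseRank1:
    def test_diagonal_k1(self):
        v, sigma = sparse_rank1(np.diag([3.0, 2.0, 1.0]), k=1)
        assert sigma == pytest.approx(3.0)
        assert list(np.flatnonzero(v)) == [0]

    def test_full_cardinality_reduces_to_dense_svd(self):
        rng = np.random.default_rng(5)
        X = rng.random((7, 5))
        _, sigma = sparse_rank1(X, k=5)
        assert sigma == pytest.approx(np.linalg.svd(X, compute_uv=False)[0], rel=1e-8)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            X = rng.integers(0, 6, size=(5, 8)).astype(float)
            if not X.any():
                continue
            best, supports = brute_force_sparse_sv(X, 2)
            v, sigma = sparse_rank1(X, 2)
            assert sigma == pytest.approx(best, rel=1e-9)
            assert tuple(np.flatnonzero(v)) in supports

    def test_unit_norm_and_support_bound(self):
        rng = np.random.default_rng(7)
        X = rng.random((10, 12))
        v, _ = sparse_rank1(X, k=4)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.count_nonzero(v) <= 4

    def test_zero_matrix_raises(self):
        with pytest.raises(NoSignalError):
            sparse_rank1(np.zeros((3, 3)), k=1)


class TestAssociateDocs:
    def test_orthogonal_rows_score_zero(self):
        X = np.diag([3.0, 2.0, 1.0])
        v = np.array([1.0, 0.0, 0.0])
        assert associate_docs(X, v, m=2) == [(0, 3.0)]

    def test_m_exceeding_scoring_docs_returns_all(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
        v = np.array([1.0, 0.0])
        assert associate_docs(X, v, m=10) == [(1, 2.0), (0, 1.0)]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(8)
        X = rng.random((8, 5))
        v = rng.random(5)
        v /= np.linalg.norm(v)
        got = associate_docs(X, v, m=3)
        scores = np.abs(X @ v)
        expected = sorted(range(8), key=lambda i: (-scores[i], i))[:3]
        assert [i for i, _ in got] == expected
        for i, s in got:
            assert s == pytest.approx(scores[i])


class TestRemoveDocs:
    def test_remove_all_rows_gives_zero_matrix(self):
        X = np.arange(1.0, 7.0).reshape(3, 2)
        out = remove_docs(X, [0, 1, 2])
        assert out.nnz == 0

    def test_frobenius_additivity(self):
        X = np.array([[3.0, 0.0], [4.0, 0.0]])  # frob2 = 25, row0 norm2 = 9
        out = remove_docs(X, [0])
        assert (out.toarray() ** 2).sum() == pytest.approx(16.0)

    def test_random_subset_identity(self):
        rng = np.random.default_rng(9)
        X = rng.random((12, 6))
        rows = [1, 4, 7]
        out = remove_docs(X, rows)
        expected = (X**2).sum() - (X[rows] ** 2).sum()
        assert (out.toarray() ** 2).sum() == pytest.approx(expected, rel=1e-12)

    def test_double_removal_rejected(self):
        X = np.eye(3)
        once = remove_docs(X, [1])
        with pytest.raises(RowRemovalError):
            remove_docs(once, [1])
        with pytest.raises(RowRemovalError):
            remove_docs(X, [0, 0])


def _two_block_corpus():
    """Block A: 10 docs on terms a0..a4 (heavier); block B: 8 docs on b0..b4."""
    rng = np.random.default_rng(11)
    a_terms = [f"a{i}" for i in range(5)]
    b_terms = [f"b{i}" for i in range(5)]
    token_lists = []
    for _ in range(10):
        token_lists.append(list(rng.choice(a_terms, size=8, replace=True)))
    for _ in range(8):
        token_lists.append(list(rng.choice(b_terms, size=5, replace=True)))
    return _tdm(token_lists), set(a_terms), set(b_terms)


class TestFitTopicModel:
    def test_two_disjoint_blocks_recovered_with_per_block_svd_sigmas(self):
        tdm, a_terms, b_terms = _two_block_corpus()
        model = fit_topic_model(tdm, SpcaConfig(k_terms=5, m_docs=10, residual_frac_stop=0.0))
        assert len(model.topics) == 2
        assert set(model.topics[0].terms) == a_terms
        assert set(model.topics[1].terms) == b_terms
        dense = tdm.values.toarray()
        cols_a = [tdm.vocabulary.index[t] for t in sorted(a_terms)]
        cols_b = [tdm.vocabulary.index[t] for t in sorted(b_terms)]
        sv_a = np.linalg.svd(dense[:10][:, cols_a], compute_uv=False)[0]
        sv_b = np.linalg.svd(dense[10:][:, cols_b], compute_uv=False)[0]
        assert model.topics[0].singular_value == pytest.approx(sv_a, rel=1e-8)
        assert model.topics[1].singular_value == pytest.approx(sv_b, rel=1e-8)
        assert model.residual_frob2_after[-1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_matrix_gives_empty_model(self):
        tdm = _tdm([["x"], ["y"]])
        tdm.values.data[:] = 0.0
        model = fit_topic_model(tdm)
        assert model.topics == ()

    def test_large_m_consumes_all_scoring_docs(self):
        tdm, a_terms, b_terms = _two_block_corpus()
        model = fit_topic_model(tdm, SpcaConfig(k_terms=5, m_docs=100, residual_frac_stop=0.0))
        # first topic eats all of block A (B rows score 0 on A's support)
        assert len(model.topics[0].doc_ids) == 10
        assert len(model.topics) == 2

    def test_monotone_residual_accounting(self):
        rng = np.random.default_rng(12)
        terms = [f"w{i}" for i in range(15)]
        token_lists = [list(rng.choice(terms, size=6, replace=True)) for _ in range(30)]
        model = fit_topic_model(_tdm(token_lists), SpcaConfig(k_terms=3, m_docs=5))
        trace = (model.original_frob2,) + model.residual_frob2_after
        assert all(b < a for a, b in zip(trace, trace[1:]))
        assert all(r >= 0 for r in trace)

    def test_determinism_bitwise(self, tmp_path):
        tdm, _, _ = _two_block_corpus()
        cfg = SpcaConfig(k_terms=5, m_docs=10)
        fit_topic_model(tdm, cfg).to_json(tmp_path / "m1.json")
        fit_topic_model(tdm, cfg).to_json(tmp_path / "m2.json")
        assert (tmp_path / "m1.json").read_bytes() == (tmp_path / "m2.json").read_bytes()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        terms = [f"w{i}" for i in range(12)]
        docs = [_doc(list(rng.choice(terms, size=6, replace=True)), f"d{i}") for i in range(25)]
        vocab = build_vocabulary(docs, min_df=1, max_df_frac=1.0)
        tdm = build_matrix(docs, vocab)
        perm = list(rng.permutation(25))
        tdm_p = build_matrix([docs[i] for i in perm], vocab)
        cfg = SpcaConfig(k_terms=4, m_docs=6, max_topics=3)
        m1 = fit_topic_model(tdm, cfg)
        m2 = fit_topic_model(tdm_p, cfg)
        for t1, t2 in zip(m1.topics, m2.topics):
            assert t1.terms == t2.terms
            assert t1.singular_value == pytest.approx(t2.singular_value, rel=1e-9)
            assert sorted(t1.doc_ids) == sorted(t2.doc_ids)

    def test_json_round_trip(self, tmp_path):
        tdm, _, _ = _two_block_corpus()
        model = fit_topic_model(tdm, SpcaConfig())
        model.to_json(tmp_path / "model.json")
        assert TopicModel.from_json(tmp_path / "model.json") == model
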