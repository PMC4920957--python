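"""Cardinality-constrained sparse rank-1 topic extraction.

Each topic is a sparse loading vector v (at most ``k_terms`` nonzero keyword
weights, unit Euclidean norm) that approximately maximizes ||X v||, its
singular value sigma = ||X v|| (higher sigma = more prevalent topic), and the
``m_docs`` documents most strongly associated with it (largest |row . v|).
Extraction alternates with *hard clustering*: the associated document rows are
zeroed from the residual, so no message can illustrate two topics, and the
squared Frobenius norm removed per topic drives the variance-explained
accounting used for model selection.

The solver is truncated power iteration with hard thresholding:

    u <- X v / ||X v||;  w <- X^T u;  v <- top-k(|w|) entries of w, renormalized

run from a deterministic family of starting points — the columns of largest
norm, their hard-thresholded Gram columns (one power step of lookahead), a
greedy forward-selected support, and the hard-thresholded dense leading
right singular vector — keeping the best sigma. This is a heuristic for an
NP-hard support search; on small problems it is routinely checked against
exhaustive support enumeration.
Ties in thresholding and scoring are broken toward the lower column/row
index, so results are reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import NoSignalError, RowRemovalError
from .term_matrix import TermDocMatrix

__all__ = [
    "SpcaConfig",
    "Topic",
    "TopicModel",
    "sparse_rank1",
    "associate_docs",
    "remove_docs",
    "fit_topic_model",
]


@dataclass(frozen=True)
class SpcaConfig:
    """Tunable parameters of the topic extraction loop.

    k_terms
        Keywords per topic (cardinality of the loading vector). Default 5.
    m_docs
        Example tweets per topic; the rows consumed by each extraction.
        Default 10 (compare 15 and 20 via :func:`model_selection.compare_models`).
    max_topics / residual_frac_stop
        Stop when the residual squared Frobenius norm drops to
        ``residual_frac_stop`` of the original, or after ``max_topics`` topics.
    tol / max_iter
        Power-iteration convergence tolerance on sigma and iteration cap.
    n_init
        Number of deterministic column starting points for the solver.
    signed_scores
        If True, associate documents by the signed projection row.v instead of
        its absolute value.
    seed
        Recorded for provenance; the default initialization is deterministic
        and does not consume randomness.
    """

    k_terms: int = 5
    m_docs: int = 10
    max_topics: int = 200
    residual_frac_stop: float = 0.05
    tol: float = 1e-9
    max_iter: int = 500
    n_init: int = 10
    signed_scores: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_terms < 1:
            raise ValueError("k_terms must be >= 1")
        if self.m_docs < 1:
            raise ValueError("m_docs must be >= 1")
        if not (0.0 <= self.residual_frac_stop < 1.0):
            raise ValueError("residual_frac_stop must be in [0, 1)")
        if self.max_topics < 1:
            raise ValueError("max_topics must be >= 1")


def _as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X, dtype=float))


def _hard_threshold(w: np.ndarray, k: int) -> np.ndarray | None:
    """Keep the k largest-|.| entries of w (ties -> lower index), renormalize."""
    if k < len(w):
        order = np.argsort(-np.abs(w), kind="stable")
        keep = order[:k]
        v = np.zeros_like(w)
        v[keep] = w[keep]
    else:
        v = w.copy()
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return None
    return v / norm


_GRAM_INIT_MAX_COLS = 2000


def _greedy_support(gram: np.ndarray, k: int) -> list[int]:
    """Forward selection on the Gram matrix: grow the support one column at a
    time, each step adding the column that maximizes the leading eigenvalue of
    the restricted Gram block (ties toward the lower index)."""
    n = gram.shape[0]
    support: list[int] = []
    chosen = np.zeros(n, dtype=bool)
    for _ in range(k):
        best_j, best_val = -1, -1.0
        for j in range(n):
            if chosen[j]:
                continue
            idx = support + [j]
            lam = float(np.linalg.eigvalsh(gram[np.ix_(idx, idx)])[-1])
            if lam > best_val + 1e-15:
                best_val, best_j = lam, j
        if best_j < 0 or best_val <= 0.0:
            break
        support.append(best_j)
        chosen[best_j] = True
    return sorted(support)


def _truncated_power(X: sp.csr_matrix, XT: sp.csr_matrix, v0: np.ndarray, k: int, tol: float, max_iter: int):
    """One truncated power run; returns (v, sigma) or None if it dies."""
    v = v0
    sigma_prev = -1.0
    for _ in range(max_iter):
        u = X @ v
        nu = np.linalg.norm(u)
        if nu == 0.0:
            return None
        w = XT @ (u / nu)
        v_new = _hard_threshold(w, k)
        if v_new is None:
            return None
        sigma = np.linalg.norm(X @ v_new)
        v = v_new
        if abs(sigma - sigma_prev) <= tol * max(1.0, sigma):
            break
        sigma_prev = sigma
    return v, float(np.linalg.norm(X @ v))


def sparse_rank1(
    X,
    k: int,
    *,
    tol: float = 1e-9,
    max_iter: int = 500,
    n_init: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Sparse leading right singular vector: max ||X v|| s.t. ||v||=1, ||v||_0 <= k.

    Deterministic: starting points are the ``n_init`` columns of largest norm
    (ties toward the lower index), their hard-thresholded Gram columns and a
    greedy forward-selected support (both while the column count keeps the
    Gram matrix cheap), plus the hard-thresholded dense leading right
    singular vector; the best sigma wins. ``seed`` is accepted for interface
    stability but unused by this initialization rule.

    Raises :class:`NoSignalError` on an all-zero matrix.
    """
    X = _as_csr(X)
    n_rows, n_cols = X.shape
    if k < 1 or k > n_cols:
        raise ValueError(f"cardinality k={k} out of range for {n_cols} columns")
    col_norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=0)).ravel())
    if not np.any(col_norms > 0):
        raise NoSignalError("matrix has no nonzero entry")
    XT = X.T.tocsr()

    inits: list[np.ndarray] = []
    order = np.argsort(-col_norms, kind="stable")
    # Gram-based starts are worth their cost only while the Gram matrix stays
    # small; beyond this bound the plain column starts carry the search.
    use_gram = n_cols <= _GRAM_INIT_MAX_COLS
    for j in order[: max(1, n_init)]:
        if col_norms[j] == 0:
            break
        e = np.zeros(n_cols)
        e[j] = 1.0
        inits.append(e)
        if use_gram:
            # one-step lookahead: the k strongest partners of column j
            g = XT @ (X @ e)
            v_g = _hard_threshold(g, k)
            if v_g is not None:
                inits.append(v_g)
    if use_gram:
        gram = (XT @ X).toarray()
        support = _greedy_support(gram, k)
        if support:
            sub = gram[np.ix_(support, support)]
            _, vecs = np.linalg.eigh(sub)
            v_greedy = np.zeros(n_cols)
            v_greedy[support] = vecs[:, -1]
            inits.append(v_greedy)
    # Extra candidate: dense leading right singular vector (plain power
    # iteration, no truncation), then hard-thresholded to the k-support.
    v_dense = inits[0].copy()
    for _ in range(100):
        u = X @ v_dense
        nu = np.linalg.norm(u)
        if nu == 0.0:
            break
        w = XT @ (u / nu)
        nw = np.linalg.norm(w)
        if nw == 0.0:
            break
        v_next = w / nw
        if np.linalg.norm(v_next - v_dense) <= 1e-12:
            v_dense = v_next
            break
        v_dense = v_next
    v_trunc = _hard_threshold(v_dense, k)
    if v_trunc is not None:
        inits.append(v_trunc)

    best_v: np.ndarray | None = None
    best_sigma = -1.0
    for v0 in inits:
        result = _truncated_power(X, XT, v0, k, tol, max_iter)
        if result is None:
            continue
        v, sigma = result
        if sigma > best_sigma * (1.0 + 1e-12):
            best_v, best_sigma = v, sigma
    if best_v is None:
        raise NoSignalError("no starting point produced a nonzero component")
    return best_v, best_sigma


def associate_docs(
    X,
    v: np.ndarray,
    m: int,
    *,
    signed: bool = False,
) -> list[tuple[int, float]]:
    """Top-m (row index, score) pairs by association score, descending.

    score_i = |row_i . v| (or the signed projection when ``signed``); rows with
    zero score are never returned, so fewer than m pairs come back when the
    residual holds fewer than m scoring documents. Ties break toward the lower
    row index.
    """
    X = _as_csr(X)
    proj = X @ v
    scores = proj if signed else np.abs(proj)
    order = np.argsort(-scores, kind="stable")
    out: list[tuple[int, float]] = []
    for i in order[:m]:
        if scores[i] <= 0.0:
            break
        out.append((int(i), float(scores[i])))
    return out


def remove_docs(X, rows: Sequence[int]) -> sp.csr_matrix:
    """Zero the listed document rows (hard clustering step).

    Raises :class:`RowRemovalError` on duplicate listing or on a row that is
    already empty (i.e. already removed). The squared Frobenius norm drops by
    exactly the sum of the removed rows' squared norms.
    """
    X = _as_csr(X)
    rows = list(rows)
    if len(set(rows)) != len(rows):
        raise RowRemovalError("a row is listed twice")
    n = X.shape[0]
    mask = np.ones(n)
    nnz_per_row = np.diff(X.indptr)
    for i in rows:
        if not (0 <= i < n):
            raise RowRemovalError(f"row {i} out of range")
        if nnz_per_row[i] == 0:
            raise RowRemovalError(f"row {i} is already empty (double removal?)")
        mask[i] = 0.0
    out = sp.diags(mask).dot(X).tocsr()
    out.eliminate_zeros()
    return out


@dataclass(frozen=True)
class Topic:
    """One extracted component: sparse keyword loading + associated documents."""

    index: int
    terms: tuple[str, ...]
    loadings: tuple[float, ...]
    singular_value: float
    doc_ids: tuple[str, ...]
    doc_scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.terms) != len(self.loadings):
            raise ValueError("terms and loadings must align")
        if len(self.doc_ids) != len(self.doc_scores):
            raise ValueError("doc_ids and doc_scores must align")
        if self.singular_value < 0:
            raise ValueError("singular_value must be >= 0")
        if any(a < b for a, b in zip(self.doc_scores, self.doc_scores[1:])):
            raise ValueError("doc_scores must be non-increasing")


@dataclass(frozen=True)
class TopicModel:
    """Ordered topics plus the residual-norm trace for variance accounting.

    Topics are reported in extraction order. Because each loading vector is a
    sparse approximation, extraction order need not be strictly descending in
    singular value — a small amount of shuffling relative to the sigma ranking
    is expected.
    """

    topics: tuple[Topic, ...]
    original_frob2: float
    residual_frob2_after: tuple[float, ...]
    config: SpcaConfig
    n_docs: int
    n_terms: int

    def __post_init__(self):
        trace = self.residual_frob2_after
        if len(trace) != len(self.topics):
            raise ValueError("one residual value per topic required")
        prev = self.original_frob2
        for r in trace:
            if r < -1e-9 or r > prev + 1e-9 * max(1.0, prev):
                raise ValueError("residual trace must be non-negative and non-increasing")
            prev = r

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_docs": self.n_docs,
            "n_terms": self.n_terms,
            "original_frob2": self.original_frob2,
            "residual_frob2_after": list(self.residual_frob2_after),
            "topics": [
                {
                    "index": t.index,
                    "terms": list(t.terms),
                    "loadings": list(t.loadings),
                    "singular_value": t.singular_value,
                    "doc_ids": list(t.doc_ids),
                    "doc_scores": list(t.doc_scores),
                }
                for t in self.topics
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TopicModel":
        obj = json.loads(Path(path).read_text("utf-8"))
        topics = tuple(
            Topic(
                index=t["index"],
                terms=tuple(t["terms"]),
                loadings=tuple(t["loadings"]),
                singular_value=t["singular_value"],
                doc_ids=tuple(t["doc_ids"]),
                doc_scores=tuple(t["doc_scores"]),
            )
            for t in obj["topics"]
        )
        return cls(
            topics=topics,
            original_frob2=obj["original_frob2"],
            residual_frob2_after=tuple(obj["residual_frob2_after"]),
            config=SpcaConfig(**obj["config"]),
            n_docs=obj["n_docs"],
            n_terms=obj["n_terms"],
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "topic": t.index,
                "singular_value": t.singular_value,
                "n_docs": len(t.doc_ids),
                "terms": " ".join(t.terms),
                "doc_ids": " ".join(t.doc_ids),
            }
            for t in self.topics
        ]
        pd.DataFrame(rows, columns=["topic", "singular_value", "n_docs", "terms", "doc_ids"]).to_csv(
            path, index=False
        )


def fit_topic_model(tdm: TermDocMatrix, config: SpcaConfig | None = None) -> TopicModel:
    """Extract topics until the residual stop rule, the topic cap, or no signal.

    Loop: sparse rank-1 on the residual -> Topic (terms = support of v,
    sigma = ||Xv||) -> top-m document association -> zero those rows ->
    record the residual squared Frobenius norm. An all-zero input yields an
    empty model rather than an error.
    """
    if config is None:
        config = SpcaConfig()
    X = tdm.values.tocsr(copy=True)
    X.eliminate_zeros()
    original = float((X.data**2).sum())
    topics: list[Topic] = []
    residual_trace: list[float] = []
    residual = original
    terms = tdm.vocabulary.terms

    while residual > config.residual_frac_stop * original and len(topics) < config.max_topics:
        try:
            v, sigma = sparse_rank1(
                X,
                config.k_terms,
                tol=config.tol,
                max_iter=config.max_iter,
                n_init=config.n_init,
            )
        except NoSignalError:
            break
        support = np.flatnonzero(v)
        assoc = associate_docs(X, v, config.m_docs, signed=config.signed_scores)
        if not assoc:
            break
        topics.append(
            Topic(
                index=len(topics),
                terms=tuple(terms[j] for j in support),
                loadings=tuple(float(v[j]) for j in support),
                singular_value=sigma,
                doc_ids=tuple(tdm.row_ids[i] for i, _ in assoc),
                doc_scores=tuple(s for _, s in assoc),
            )
        )
        X = remove_docs(X, [i for i, _ in assoc])
        residual = float((X.data**2).sum())
        residual_trace.append(residual)

    return TopicModel(
        topics=tuple(topics),
        original_frob2=original,
        residual_frob2_after=tuple(residual_trace),
        config=config,
        n_docs=len(tdm.row_ids),
        n_terms=len(terms),
    )
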