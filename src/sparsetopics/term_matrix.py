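"""Weighted bag-of-words document-term matrix construction.

Entry (i, j) is ``sqrt(multiplicity_i) * tf(term_j in doc_i)``, so a message
collapsed from c identical copies contributes c times the squared Frobenius
norm of a singleton — the variance accounting downstream then weighs messages
by how often they actually appeared. Word order is ignored throughout; all
analysis rests on patterns of association between words.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import EmptyVocabularyError
from .preprocess import Document

__all__ = ["Vocabulary", "TermDocMatrix", "build_vocabulary", "build_matrix"]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered term list (lexicographic) with 0-based dense column indices."""

    terms: tuple[str, ...]
    doc_freq: tuple[int, ...]

    def __post_init__(self):
        if len(self.terms) != len(self.doc_freq):
            raise ValueError("terms and doc_freq must align")
        if list(self.terms) != sorted(set(self.terms)):
            raise ValueError("terms must be sorted and distinct")

    @property
    def index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for term, df in zip(self.terms, self.doc_freq):
                fh.write(f"{term}\t{df}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        terms, dfs = [], []
        for line in Path(path).read_text("utf-8").splitlines():
            if not line:
                continue
            term, _, df = line.partition("\t")
            terms.append(term)
            dfs.append(int(df))
        return cls(terms=tuple(terms), doc_freq=tuple(dfs))


def build_vocabulary(
    docs: Sequence[Document],
    min_df: int = 2,
    max_df_frac: float = 0.95,
    *,
    stop_terms: frozenset[str] = frozenset(),
) -> Vocabulary:
    """Terms with document frequency in ``[min_df, max_df_frac * n_docs]``.

    Hapax pruning (min_df=2 by default) removes terms that cannot form word
    associations; the max_df cap removes near-ubiquitous terms (typically the
    collection query phrases themselves) that would otherwise leak into every
    component. Frequency counts documents, not multiplicities.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from zero documents")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    df_counter: Counter[str] = Counter()
    for doc in docs:
        df_counter.update(set(doc.tokens))
    max_df = max_df_frac * len(docs)
    kept = sorted(
        t for t, df in df_counter.items() if min_df <= df <= max_df and t not in stop_terms
    )
    if not kept:
        raise EmptyVocabularyError(
            f"document-frequency pruning (min_df={min_df}, max_df_frac={max_df_frac}) "
            f"removed all {len(df_counter)} candidate terms"
        )
    return Vocabulary(terms=tuple(kept), doc_freq=tuple(df_counter[t] for t in kept))


@dataclass(frozen=True)
class TermDocMatrix:
    """Documents x terms weighted count matrix with row/column index maps."""

    values: sp.csr_matrix
    row_ids: tuple[str, ...]
    vocabulary: Vocabulary
    row_scale: np.ndarray  # sqrt(multiplicity) actually applied to each row

    def __post_init__(self):
        n, v = self.values.shape
        if n != len(self.row_ids) or v != len(self.vocabulary):
            raise ValueError("matrix shape does not match row ids / vocabulary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def frob2(self) -> float:
        """Squared Frobenius norm of the weighted matrix."""
        return float((self.values.data**2).sum())

    def save(self, directory: str | Path, prefix: str = "matrix") -> None:
        """Persist as MatrixMarket plus sidecar row-id/vocabulary text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / f"{prefix}.mtx"), self.values)
        (directory / f"{prefix}.rows.txt").write_text(
            "".join(f"{rid}\t{float(s)!r}\n" for rid, s in zip(self.row_ids, self.row_scale)),
            encoding="utf-8",
        )
        self.vocabulary.to_file(directory / f"{prefix}.vocab.txt")

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "matrix") -> "TermDocMatrix":
        directory = Path(directory)
        values = sp.csr_matrix(mmread(str(directory / f"{prefix}.mtx")))
        row_ids, scales = [], []
        for line in (directory / f"{prefix}.rows.txt").read_text("utf-8").splitlines():
            rid, _, s = line.partition("\t")
            row_ids.append(rid)
            scales.append(float(s))
        vocab = Vocabulary.from_file(directory / f"{prefix}.vocab.txt")
        return cls(values=values, row_ids=tuple(row_ids), vocabulary=vocab, row_scale=np.array(scales))


def build_matrix(
    docs: Sequence[Document],
    vocab: Vocabulary,
    tf_mode: Literal["count", "log1p"] = "count",
) -> TermDocMatrix:
    """Assemble the weighted matrix; row order follows document order."""
    if len(vocab) == 0:
        raise EmptyVocabularyError("vocabulary is empty")
    index = vocab.index
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    scales = np.array([math.sqrt(doc.multiplicity) for doc in docs])
    for i, doc in enumerate(docs):
        counts = Counter(tok for tok in doc.tokens if tok in index)
        for term, c in counts.items():
            tf = float(c) if tf_mode == "count" else math.log1p(c)
            rows.append(i)
            cols.append(index[term])
            data.append(scales[i] * tf)
    values = sp.csr_matrix((data, (rows, cols)), shape=(len(docs), len(vocab)))
    return TermDocMatrix(
        values=values,
        row_ids=tuple(doc.doc_id for doc in docs),
        vocabulary=vocab,
        row_scale=scales,
    )
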