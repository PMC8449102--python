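"""Word-meaning models: distributional embedding tables and the 1-D abstractness scale.

Two semantic models are compared against brain activity throughout this
package: a high-dimensional distributional model (word2vec-style vectors,
one per stimulus word) and a one-dimensional abstractness model derived
from behavioural category-typicality ratings on a 1-7 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingTable",
    "AbstractnessModel",
    "read_word2vec_text",
    "write_word2vec_text",
    "select_words",
    "abstractness_from_ratings",
]


@dataclass
class EmbeddingTable:
    """An ordered set of word labels with one D-dimensional real vector each.

    Parameters
    ----------
    words : list of str
        Unique word labels, in stimulus order.
    vectors : ndarray of shape (n_words, dim)
        One embedding vector per word; all values finite.
    categories : list of str, optional
        Per-word category label (e.g. ``"abstract"`` / ``"concrete"``).
    """

    words: list[str]
    vectors: np.ndarray
    categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.words = list(self.words)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (words x dim) array")
        if len(self.words) != self.vectors.shape[0]:
            raise ValueError(
                f"{len(self.words)} words but {self.vectors.shape[0]} vector rows"
            )
        if self.vectors.shape[1] < 1:
            raise ValueError("embedding dimensionality must be >= 1")
        if len(set(self.words)) != len(self.words):
            dupes = sorted({w for w in self.words if self.words.count(w) > 1})
            raise ValueError(f"duplicate word labels: {dupes}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors contain non-finite values")
        if self.categories is not None:
            self.categories = list(self.categories)
            if len(self.categories) != len(self.words):
                raise ValueError("categories must align with words")

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class AbstractnessModel:
    """One abstractness score per word on the behavioural 1-7 rating scale."""

    words: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.words = list(self.words)
        if self.scores.ndim != 1 or len(self.scores) != len(self.words):
            raise ValueError("scores must be a 1-D array aligned with words")
        if np.any(self.scores < 1.0) or np.any(self.scores > 7.0):
            raise ValueError("abstractness scores must lie within [1, 7]")


def read_word2vec_text(path) -> EmbeddingTable:
    """Read an embedding table in word2vec text format.

    The format is a header line ``"N D"`` followed by N lines of one word
    and D space-separated floats. File order is preserved.

    Raises
    ------
    ValueError
        On header/row mismatches, duplicate words or non-numeric fields,
        naming the offending line number (1-based).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise ValueError(f"line 1: expected header 'N D', got {header!r}")
        try:
            n, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"line 1: non-integer header fields {parts}") from None
        if n < 1 or dim < 1:
            raise ValueError(f"line 1: header counts must be positive, got {n} {dim}")
        words: list[str] = []
        vectors = np.empty((n, dim), dtype=float)
        seen: set[str] = set()
        for row in range(n):
            line = fh.readline()
            lineno = row + 2
            if not line:
                raise ValueError(
                    f"line {lineno}: file ended after {row} of {n} declared rows"
                )
            fields = line.split()
            if len(fields) != dim + 1:
                raise ValueError(
                    f"line {lineno}: expected 1 word + {dim} values, "
                    f"got {len(fields)} fields"
                )
            word = fields[0]
            if word in seen:
                raise ValueError(f"line {lineno}: duplicate word {word!r}")
            seen.add(word)
            try:
                vectors[row] = [float(x) for x in fields[1:]]
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-numeric vector field for word {word!r}"
                ) from None
            words.append(word)
        extra = fh.readline()
        if extra.strip():
            raise ValueError(f"line {n + 2}: trailing data beyond {n} declared rows")
    return EmbeddingTable(words=words, vectors=vectors)


def write_word2vec_text(table: EmbeddingTable, path, fmt: str = "%.6g") -> None:
    """Write an embedding table in word2vec text format (UTF-8, space-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{table.n_words} {table.dim}\n")
        for word, vec in zip(table.words, table.vectors):
            fh.write(word + " " + " ".join(fmt % v for v in vec) + "\n")


def select_words(table: EmbeddingTable, stimulus_list: list[str]) -> EmbeddingTable:
    """Restrict and reorder a table to a stimulus word list.

    Word matching is case-sensitive. Raises ``KeyError`` listing every
    stimulus word absent from the table.
    """
    index = {w: i for i, w in enumerate(table.words)}
    missing = [w for w in stimulus_list if w not in index]
    if missing:
        raise KeyError(f"words absent from embedding table: {missing}")
    rows = [index[w] for w in stimulus_list]
    cats = None
    if table.categories is not None:
        cats = [table.categories[i] for i in rows]
    return EmbeddingTable(
        words=list(stimulus_list), vectors=table.vectors[rows], categories=cats
    )


def abstractness_from_ratings(
    ratings: pd.DataFrame, abstract_category_label: str = "abstract"
) -> AbstractnessModel:
    """Extract the abstractness scale from category-typicality ratings.

    ``ratings`` is a long-format table with columns ``respondent``, ``word``,
    ``category`` and ``rating`` (1-7 scale). The score of each word is the
    mean over respondents of its rating on the abstract-words category, so
    the result is invariant to respondent order.
    """
    required = {"respondent", "word", "category", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    sub = ratings[ratings["category"] == abstract_category_label]
    words = list(pd.unique(ratings["word"]))
    means = sub.groupby("word", sort=False)["rating"].mean()
    unrated = [w for w in words if w not in means.index]
    if unrated:
        raise ValueError(
            f"no ratings on category {abstract_category_label!r} for words: {unrated}"
        )
    return AbstractnessModel(words=words, scores=means.reindex(words).to_numpy())
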