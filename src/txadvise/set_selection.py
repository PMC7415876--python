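"""Advisor-set subset selection for resource-limited advising.

The training signal is an examples × vectors matrix of scaled AUC values:
entry (i, j) is the estimator score of the assembly built for training
sample i under parameter vector j.  A subset's advising score is the mean
over samples of the best score any of its vectors achieves — exactly the
training-set advising AUC a user of that subset would see.  Greedy
forward selection builds nested subsets for k = 1..k_max; an exhaustive
mode gives the true optimum on small instances and serves as the oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AucMatrix:
    """Examples × parameter-vectors table of scaled AUC values."""

    examples: list[str]
    vector_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.examples), len(self.vector_labels)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.examples)} examples x {len(self.vector_labels)} vectors"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1e4):
            raise ValidationError("AUC entries must lie in [0, 1e4]")
        zero_rows = [e for e, row in zip(self.examples, self.values) if row.max() == 0]
        if zero_rows:
            logger.warning("examples with all-zero AUC rows: %s", zero_rows)

    @property
    def n_vectors(self) -> int:
        return len(self.vector_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.examples, columns=self.vector_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AucMatrix":
        return cls(
            examples=[str(i) for i in df.index],
            vector_labels=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    @classmethod
    def read_tsv(cls, source: str | Path | IO[str]) -> "AucMatrix":
        return cls.from_frame(pd.read_csv(source, sep="\t", index_col=0))

    def write_tsv(self, sink: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(sink, sep="\t")


def advising_score(m: AucMatrix, subset: Sequence[int]) -> float:
    """Mean over examples of the best AUC among the subset's vectors."""
    if len(subset) == 0:
        raise ValidationError("subset must be non-empty")
    idx = list(subset)
    if any(i < 0 or i >= m.n_vectors for i in idx):
        raise ValidationError(f"subset indices out of range: {idx}")
    return float(m.values[:, idx].max(axis=1).mean())


def greedy_subsets(m: AucMatrix, k_max: int) -> list[list[int]]:
    """Nested greedy subsets for k = 1..k_max.

    Each step adds the vector with the largest marginal gain in advising
    score, ties broken by the lowest vector index (so once no vector
    strictly helps, the remaining slots fill in index order).
    """
    if not 1 <= k_max <= m.n_vectors:
        raise ValidationError(f"k_max must be in [1, {m.n_vectors}], got {k_max}")
    chosen: list[int] = []
    best_per_row = np.zeros(len(m.examples))
    out: list[list[int]] = []
    for _ in range(k_max):
        gains = []
        for j in range(m.n_vectors):
            if j in chosen:
                continue
            score = float(np.maximum(best_per_row, m.values[:, j]).mean())
            gains.append((score, -j))
        score, neg_j = max(gains)  # highest score; ties -> lowest index
        j = -neg_j
        chosen.append(j)
        best_per_row = np.maximum(best_per_row, m.values[:, j])
        out.append(list(chosen))
    return out


def exhaustive_subset(m: AucMatrix, k: int, budget: int = 500_000) -> list[int]:
    """The exact argmax subset of size ``k`` (ties: lexicographically smallest).

    Refuses instances where C(n, k) exceeds ``budget`` — use
    :func:`greedy_subsets` there.
    """
    if not 1 <= k <= m.n_vectors:
        raise ValidationError(f"k must be in [1, {m.n_vectors}], got {k}")
    n_combos = comb(m.n_vectors, k)
    if n_combos > budget:
        raise ValidationError(
            f"C({m.n_vectors},{k}) = {n_combos} exceeds budget {budget}; "
            "use greedy_subsets instead"
        )
    best_subset: tuple[int, ...] | None = None
    best_score = -1.0
    for subset in combinations(range(m.n_vectors), k):
        score = float(m.values[:, list(subset)].max(axis=1).mean())
        if score > best_score:  # strict > keeps the lexicographically first tie
            best_subset, best_score = subset, score
    return list(best_subset)
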