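"""Component similarity, similarity matrices, greedy matching, alignment.

The matching step that precedes rearrangement works on a component
similarity matrix.  Each entry scores one helix of structure A against one
helix of structure B on two features:

* component length  — min/max ratio of full spans,
* stem length       — min/max ratio of base-pair counts,

combined by default as their product (``d1``).  Relative start position is
a third feature, used only to break ties between equally similar pairs.

Matching is greedy: repeatedly take the largest remaining entry; if it
reaches the threshold ``epsilon`` the pair is fixed and its row and column
retire; once nothing reaches the threshold, leftover rows are deletions
(A-only components) and leftover columns insertions (B-only components).

A separate Needleman-Wunsch alignment over the ordered component lists
gives a global similarity score and percentage, used to report how similar
two structures are before and after rearrangement.

Published similarity matrices (e.g. ones computed with the CompPSA feature
measure, whose internal equations this package does not reproduce) can be
supplied as TSV and fed straight into the greedy matcher, bypassing ``d1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .structures import Component, SecondaryStructure, full_length

__all__ = [
    "FeatureWeights",
    "SimilarityMatrix",
    "Assignment",
    "component_length_sim",
    "stem_length_sim",
    "position_sim",
    "d1",
    "build_matrix",
    "position_matrix",
    "greedy_assign",
    "align_score",
    "score_percentage",
]

_TIE_TOL = 1e-9  # entries closer than this count as tied maxima


@dataclass(frozen=True)
class FeatureWeights:
    """Feature weights and matching threshold.

    w_cl, w_sl, w_p
        weights of the component-length, stem-length and position features.
        The product combiner ignores ``w_cl``/``w_sl`` (both features enter
        once); ``w_p`` only matters for the alignment score.
    epsilon
        minimum similarity for two components to be matched (0.6 suits
        similar structures; 0.8 is a better preset for dissimilar ones).
    combiner
        ``"product"`` (default) or ``"weighted_mean"``.
    """

    w_cl: float = 1.0
    w_sl: float = 1.0
    w_p: float = 0.0
    epsilon: float = 0.6
    combiner: str = "product"

    def __post_init__(self) -> None:
        if self.combiner not in ("product", "weighted_mean"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if min(self.w_cl, self.w_sl, self.w_p) < 0:
            raise ValueError("weights must be non-negative")
        if self.combiner == "weighted_mean" and self.w_cl + self.w_sl == 0:
            raise ValueError("weighted_mean needs w_cl + w_sl > 0")


def component_length_sim(a: Component, b: Component) -> float:
    fa, fb = full_length(a), full_length(b)
    return min(fa, fb) / max(fa, fb)


def stem_length_sim(a: Component, b: Component) -> float:
    return min(a.stem_len, b.stem_len) / max(a.stem_len, b.stem_len)


def position_sim(a: Component, b: Component, len_a: int, len_b: int) -> float:
    """1 minus the difference of relative start positions."""
    return 1.0 - abs(a.ob / len_a - b.ob / len_b)


def d1(
    a: Component,
    b: Component,
    w: FeatureWeights = FeatureWeights(),
    len_a: Optional[int] = None,
    len_b: Optional[int] = None,
) -> float:
    """Two-feature similarity of a pair of components, in [0, 1].

    Position does not participate; it is a tie-breaker only.  ``len_a`` and
    ``len_b`` are accepted for interface symmetry and ignored.
    """
    cl = component_length_sim(a, b)
    sl = stem_length_sim(a, b)
    if w.combiner == "product":
        return cl * sl
    return (w.w_cl * cl + w.w_sl * sl) / (w.w_cl + w.w_sl)


@dataclass(frozen=True)
class SimilarityMatrix:
    """m x n component-similarity grid with row/column labels."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match labels "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        """Read a labelled TSV: first row column labels, first column row
        labels, cells decimal scores."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            row_labels=tuple(str(x) for x in df.index),
            col_labels=tuple(str(x) for x in df.columns),
            values=df.to_numpy(dtype=float),
        )


def build_matrix(
    A: SecondaryStructure, B: SecondaryStructure, w: FeatureWeights = FeatureWeights()
) -> SimilarityMatrix:
    """Similarity matrix with d1 entries; rows are A's components."""
    vals = np.array(
        [[d1(a, b, w) for b in B.components] for a in A.components], dtype=float
    ).reshape(len(A), len(B))
    return SimilarityMatrix(
        row_labels=tuple(f"{A.name}{c.index}" for c in A.components),
        col_labels=tuple(f"{B.name}{c.index}" for c in B.components),
        values=vals,
    )


def position_matrix(A: SecondaryStructure, B: SecondaryStructure) -> np.ndarray:
    """Pairwise position similarities, for greedy tie-breaking."""
    return np.array(
        [
            [position_sim(a, b, A.length, B.length) for b in B.components]
            for a in A.components
        ],
        dtype=float,
    ).reshape(len(A), len(B))


@dataclass(frozen=True)
class Assignment:
    """Outcome of component matching.

    ``matches`` holds (a_index, b_index, score) triples in the order the
    greedy matcher fixed them; ``deleted`` are A components left unmatched,
    ``inserted`` B components left unmatched (1-based indices).
    """

    matches: tuple[tuple[int, int, float], ...]
    deleted: tuple[int, ...]
    inserted: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matches", tuple(self.matches))
        object.__setattr__(self, "deleted", tuple(sorted(self.deleted)))
        object.__setattr__(self, "inserted", tuple(sorted(self.inserted)))
        a_seen = [m[0] for m in self.matches] + list(self.deleted)
        b_seen = [m[1] for m in self.matches] + list(self.inserted)
        if len(set(a_seen)) != len(a_seen) or len(set(b_seen)) != len(b_seen):
            raise ValueError("each component may appear at most once")

    @property
    def n_a(self) -> int:
        return len(self.matches) + len(self.deleted)

    @property
    def n_b(self) -> int:
        return len(self.matches) + len(self.inserted)

    def partner_of_b(self, b_index: int) -> Optional[int]:
        for ai, bi, _ in self.matches:
            if bi == b_index:
                return ai
        return None


def greedy_assign(
    m: SimilarityMatrix,
    tiebreak_positions: Optional[np.ndarray] = None,
    epsilon: float = 0.6,
) -> Assignment:
    """Greedy threshold matching on a similarity matrix.

    Repeatedly selects the maximum remaining entry; a pair is fixed when
    its score is >= ``epsilon``, and its row and column are retired.  Ties
    on the maximum are broken by the larger position similarity (when
    ``tiebreak_positions`` is given) and then by the lower (row, column)
    index pair, which makes the result deterministic.
    """
    vals = m.values
    n_rows, n_cols = vals.shape
    if tiebreak_positions is not None:
        tiebreak_positions = np.asarray(tiebreak_positions, dtype=float)
        if tiebreak_positions.shape != vals.shape:
            raise ValueError("tiebreak_positions shape must match the matrix")
    rows = set(range(n_rows))
    cols = set(range(n_cols))
    matches: list[tuple[int, int, float]] = []
    while rows and cols:
        best = max(vals[i, j] for i in rows for j in cols)
        if best < epsilon:
            break
        tied = [
            (i, j)
            for i in sorted(rows)
            for j in sorted(cols)
            if vals[i, j] >= best - _TIE_TOL
        ]
        if len(tied) > 1 and tiebreak_positions is not None:
            top = max(tiebreak_positions[i, j] for i, j in tied)
            tied = [
                (i, j) for i, j in tied if tiebreak_positions[i, j] >= top - _TIE_TOL
            ]
        i, j = tied[0]  # lowest (row, col) among remaining ties
        matches.append((i + 1, j + 1, float(vals[i, j])))
        rows.remove(i)
        cols.remove(j)
    return Assignment(
        matches=tuple(matches),
        deleted=tuple(i + 1 for i in sorted(rows)),
        inserted=tuple(j + 1 for j in sorted(cols)),
    )


def _align_pair_score(
    a: Component, b: Component, w: FeatureWeights, len_a: int, len_b: int
) -> float:
    base = d1(a, b, w)
    if w.w_p <= 0:
        return base
    pos = position_sim(a, b, len_a, len_b)
    if w.combiner == "product":
        return base * pos
    return (w.w_cl * component_length_sim(a, b) + w.w_sl * stem_length_sim(a, b)
            + w.w_p * pos) / (w.w_cl + w.w_sl + w.w_p)


def align_score(
    A: SecondaryStructure, B: SecondaryStructure, w: FeatureWeights = FeatureWeights()
) -> float:
    """Optimal global alignment score of the two ordered component lists.

    Needleman-Wunsch over components with match score ``d1`` (plus a
    position term when ``w_p > 0``) and gap score 0, so the optimum is the
    best-scoring order-preserving pairing.  Aligning a structure with
    itself scores its component count.
    """
    m, n = len(A), len(B)
    if m == 0 or n == 0:
        return 0.0
    dp = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _align_pair_score(
                A.components[i - 1], B.components[j - 1], w, A.length, B.length
            )
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1] + s)
    return float(dp[m, n])


def score_percentage(
    A: SecondaryStructure, B: SecondaryStructure, w: FeatureWeights = FeatureWeights()
) -> float:
    """Alignment score normalised by the larger self-score, as a
    percentage in [0, 100].  Two empty structures count as identical."""
    denom = max(align_score(A, A, w), align_score(B, B, w))
    if denom == 0.0:
        return 100.0 if len(A) == 0 and len(B) == 0 else 0.0
    return 100.0 * align_score(A, B, w) / denom
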