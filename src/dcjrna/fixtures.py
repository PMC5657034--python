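"""Synthetic structures, perturbations, reference data and a BFS oracle.

This module provides everything needed to exercise the pipeline without
external data:

* a seeded generator of valid non-crossing secondary structures,
* perturbation operators (delete / insert / swap / resize) that emulate
  how related structures differ,
* ``duplicate_structure``, the side-by-side doubling construction used to
  build scalability series,
* loaders for the bundled example structures and published
  component-similarity matrices (computed with the CompPSA feature
  measure, which this package does not reimplement), and
* ``bfs_dcj_distance``, an exhaustive breadth-first search over single DCJ
  operations that serves as an independent oracle for the closed-form
  distance on small gene sets.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterator, Optional

from .rearrangement import AdjacencySet, GenomeError, _check_same_genes
from .similarity import SimilarityMatrix
from .structures import (
    Component,
    SecondaryStructure,
    ValidationError,
    parse_component_text,
)

__all__ = [
    "GeneratorConfig",
    "random_structure",
    "duplicate_structure",
    "delete_components",
    "insert_component",
    "swap_adjacent_blocks",
    "resize_stem",
    "bfs_dcj_distance",
    "bfs_dcj_distance_map",
    "dcj_neighbors",
    "enumerate_adjacency_sets",
    "load_structure",
    "load_matrix",
    "BUNDLED_STRUCTURES",
    "BUNDLED_MATRICES",
]

# smallest footprint of one hairpin: stem down, loop, stem up
def _min_span(min_stem: int, min_loop: int) -> int:
    return 2 * min_stem + min_loop


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random structure generator.

    ``min_stem`` defaults to 2 base pairs and ``min_loop`` to 3 unpaired
    bases, the shortest hairpin loop that is sterically plausible.
    """

    n_components: int
    length: int
    seed: int = 0
    min_stem: int = 2
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.n_components < 0 or self.length < 1:
            raise ValueError("need n_components >= 0 and length >= 1")
        if self.min_stem < 1 or self.min_loop < 1:
            raise ValueError("min_stem and min_loop must be >= 1")


def random_structure(cfg: GeneratorConfig) -> SecondaryStructure:
    """Generate a valid structure with exactly ``cfg.n_components``
    helices, nested or juxtaposed at random, deterministically per seed."""
    need = cfg.n_components * _min_span(cfg.min_stem, cfg.min_loop)
    if need > cfg.length:
        raise ValueError(
            f"{cfg.n_components} components need at least {need} bases; "
            f"length {cfg.length} is too short"
        )
    rng = random.Random(cfg.seed)
    tuples: list[tuple[int, int, int]] = []
    _fill_interval(rng, 1, cfg.length, cfg.n_components, cfg, tuples)
    return SecondaryStructure.from_tuples(
        f"sim{cfg.seed}", cfg.length, tuples
    )


def _fill_interval(
    rng: random.Random,
    lo: int,
    hi: int,
    k: int,
    cfg: GeneratorConfig,
    out: list[tuple[int, int, int]],
    is_loop: bool = False,
) -> None:
    """Place k helices inside [lo, hi], recursing into loops and tails."""
    if k == 0:
        return
    unit = _min_span(cfg.min_stem, cfg.min_loop)
    space = hi - lo + 1
    # leading gap, keeping room for all k helices
    gap = rng.randint(0, space - k * unit)
    ob = lo + gap
    space_after_gap = hi - ob + 1
    # helices nested inside this one vs. laid out after it
    inner = rng.randint(0, k - 1)
    after = k - 1 - inner
    # choose this helix's span so that the loop fits `inner` helices and
    # the remaining interval fits `after`
    min_here = unit + inner * unit
    max_here = space_after_gap - after * unit
    if is_loop and gap == 0:
        # keep the helix off at least one end of the enclosing loop, else
        # it would stack seamlessly onto the parent stem and the helix
        # decomposition would no longer be canonical
        max_here = space_after_gap - max(after * unit, 1)
    span = rng.randint(min_here, max_here)
    # choose stem length within what the loop/span allows; an occupied
    # loop keeps one spare base so children cannot abut both stem ends
    needed_loop = max(cfg.min_loop, inner * unit + (1 if inner else 0))
    max_stem = (span - needed_loop) // 2
    stem = rng.randint(cfg.min_stem, max(cfg.min_stem, max_stem))
    end = ob + span - 1
    cb = end - stem + 1
    out.append((ob, cb, stem))
    _fill_interval(rng, ob + stem, cb - 1, inner, cfg, out, is_loop=True)
    _fill_interval(rng, end + 1, hi, after, cfg, out, is_loop=False)


def duplicate_structure(s: SecondaryStructure) -> SecondaryStructure:
    """Concatenate two copies of ``s`` side by side; the second copy's
    coordinates are shifted by ``s.length``."""
    tuples = [(c.ob, c.cb, c.stem_len) for c in s.components]
    tuples += [
        (c.ob + s.length, c.cb + s.length, c.stem_len) for c in s.components
    ]
    return SecondaryStructure.from_tuples(
        f"{s.name}_x2", 2 * s.length, tuples
    )


# --- perturbations --------------------------------------------------------


def delete_components(
    s: SecondaryStructure, k: int, rng: random.Random
) -> SecondaryStructure:
    """Remove ``k`` randomly chosen helices (coordinates untouched)."""
    if not 0 <= k <= len(s):
        raise ValueError(f"cannot delete {k} of {len(s)} components")
    keep = sorted(rng.sample(range(len(s)), len(s) - k))
    tuples = [
        (c.ob, c.cb, c.stem_len) for i, c in enumerate(s.components) if i in set(keep)
    ]
    return SecondaryStructure.from_tuples(f"{s.name}_del{k}", s.length, tuples)


def _free_runs(s: SecondaryStructure) -> list[tuple[int, int]]:
    """Maximal runs of bases not covered by any stem."""
    occupied = [False] * (s.length + 2)
    for c in s.components:
        for k in range(c.stem_len):
            occupied[c.ob + k] = occupied[c.cb + k] = True
    runs, start = [], None
    for pos in range(1, s.length + 1):
        if not occupied[pos] and start is None:
            start = pos
        elif occupied[pos] and start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, s.length))
    return runs


def insert_component(
    s: SecondaryStructure,
    rng: random.Random,
    min_stem: int = 2,
    min_loop: int = 3,
) -> SecondaryStructure:
    """Add one minimal hairpin in a free stretch of the backbone."""
    unit = _min_span(min_stem, min_loop)
    candidates = [(a, b) for a, b in _free_runs(s) if b - a + 1 >= unit]
    if not candidates:
        raise ValidationError(f"{s.name}: no free stretch fits a new hairpin")
    a, b = candidates[rng.randrange(len(candidates))]
    ob = rng.randint(a, b - unit + 1)
    cb = ob + min_stem + min_loop
    tuples = [(c.ob, c.cb, c.stem_len) for c in s.components]
    tuples.append((ob, cb, min_stem))
    return SecondaryStructure.from_tuples(f"{s.name}_ins", s.length, tuples)


def _subtree(s: SecondaryStructure, root: Component) -> list[Component]:
    lo, hi = root.span
    return [c for c in s.components if lo <= c.ob and c.span[1] <= hi]


def swap_adjacent_blocks(
    s: SecondaryStructure, rng: random.Random
) -> SecondaryStructure:
    """Swap two adjacent sibling helix subtrees (order perturbation).

    Siblings are components whose spans are disjoint and that share the
    same set of enclosing components; the two blocks trade places and all
    nested coordinates shift accordingly.
    """
    def parent_set(c: Component) -> frozenset[int]:
        return frozenset(
            o.index
            for o in s.components
            if o is not c and o.ob <= c.ob and c.span[1] <= o.span[1]
        )

    pairs = [
        (x, y)
        for x, y in combinations(s.components, 2)
        if x.span[1] < y.ob
        and parent_set(x) == parent_set(y)
        and not any(x.span[1] < c.ob < y.ob for c in s.components)
    ]
    if not pairs:
        raise ValidationError(f"{s.name}: no adjacent sibling blocks to swap")
    x, y = pairs[rng.randrange(len(pairs))]
    bx = _subtree(s, x)
    by = _subtree(s, y)
    in_bx = {c.index for c in bx}
    in_by = {c.index for c in by}
    wx = x.span[1] - x.span[0] + 1
    wy = y.span[1] - y.span[0] + 1
    shift_y = x.span[0] - y.span[0]          # move block y to x's start
    shift_x = (y.span[1] - wx + 1) - x.span[0]  # move block x to y's end
    tuples = []
    for c in s.components:
        if c.index in in_by:
            d = shift_y
        elif c.index in in_bx:
            d = shift_x
        else:
            d = 0
        tuples.append((c.ob + d, c.cb + d, c.stem_len))
    return SecondaryStructure.from_tuples(f"{s.name}_swap", s.length, tuples)


def resize_stem(
    s: SecondaryStructure, rng: random.Random, delta: int = 1
) -> SecondaryStructure:
    """Grow or shrink one randomly chosen stem by ``delta`` base pairs,
    keeping the structure valid (falls back over candidates)."""
    order = list(range(len(s)))
    rng.shuffle(order)
    for idx in order:
        tuples = [(c.ob, c.cb, c.stem_len) for c in s.components]
        ob, cb, sl = tuples[idx]
        if sl + delta < 1:
            continue
        tuples[idx] = (ob, cb - delta, sl + delta)
        try:
            return SecondaryStructure.from_tuples(
                f"{s.name}_resize", s.length, tuples
            )
        except ValidationError:
            continue
    raise ValidationError(f"{s.name}: no stem can change by {delta}")


# --- exhaustive DCJ oracle ------------------------------------------------


_RawState = frozenset  # frozenset of frozensets of extremities


def _raw_neighbors(state: _RawState) -> Iterator[_RawState]:
    elements = tuple(state)
    for u, v in combinations(elements, 2):
        rest = state - {u, v}
        if len(u) == 2 and len(v) == 2:
            (a, b), (c, d) = sorted(u), sorted(v)
            yield rest | {frozenset({a, c}), frozenset({b, d})}
            yield rest | {frozenset({a, d}), frozenset({b, c})}
        elif len(u) + len(v) == 3:
            adj, tel = (u, v) if len(u) == 2 else (v, u)
            (a, b), (r,) = sorted(adj), tuple(tel)
            yield rest | {frozenset({a, r}), frozenset({b})}
            yield rest | {frozenset({b, r}), frozenset({a})}
        else:  # two telomeres -> fuse into an adjacency
            yield rest | {u | v}
    # split an adjacency into two telomeres
    for u in elements:
        if len(u) == 2:
            a, b = sorted(u)
            yield (state - {u}) | {frozenset({a}), frozenset({b})}


def dcj_neighbors(state: AdjacencySet) -> Iterator[AdjacencySet]:
    """All states one DCJ operation away (cuts/joins on <= 2 elements)."""
    for raw in _raw_neighbors(frozenset(state.elements)):
        yield AdjacencySet(raw)


def _guard(a: AdjacencySet, b: Optional[AdjacencySet], max_genes: int) -> None:
    if b is not None:
        _check_same_genes(a, b)
    if len(a.genes) > max_genes:
        raise GenomeError(
            f"BFS oracle limited to {max_genes} genes, got {len(a.genes)}"
        )


def bfs_dcj_distance(
    a: AdjacencySet, b: AdjacencySet, max_genes: int = 5
) -> int:
    """Breadth-first-search minimum number of DCJ operations from ``a``
    to ``b``; exhaustive, guarded to small gene sets."""
    _guard(a, b, max_genes)
    start = frozenset(a.elements)
    goal = frozenset(b.elements)
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        state, dist = queue.popleft()
        for nxt in _raw_neighbors(state):
            if nxt == goal:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, dist + 1))
    raise GenomeError("target unreachable")  # cannot happen on a shared gene set


def bfs_dcj_distance_map(
    a: AdjacencySet, max_genes: int = 5
) -> "dict[AdjacencySet, int]":
    """BFS distances from ``a`` to every reachable genome state over the
    same genes (i.e. all of them).  Handy for exhaustive oracle sweeps."""
    _guard(a, None, max_genes)
    start = frozenset(a.elements)
    dist: dict[_RawState, int] = {start: 0}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        for nxt in _raw_neighbors(state):
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                queue.append(nxt)
    return {AdjacencySet(k): v for k, v in dist.items()}


def enumerate_adjacency_sets(n_genes: int) -> list[AdjacencySet]:
    """Every genome state over genes 1..n: all partitions of the 2n
    extremities into unordered pairs and singletons."""
    exts = [(g, e) for g in range(1, n_genes + 1) for e in ("t", "h")]

    def rec(remaining: tuple) -> Iterator[tuple[frozenset, ...]]:
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for tail in rec(rest):
            yield (frozenset({first}),) + tail
        for i, other in enumerate(rest):
            pair = frozenset({first, other})
            rest2 = rest[:i] + rest[i + 1 :]
            for tail in rec(rest2):
                yield (pair,) + tail

    return [AdjacencySet(els) for els in rec(tuple(exts))]


# --- bundled reference data -----------------------------------------------

BUNDLED_STRUCTURES = ("trna_leu", "trna_ala")
BUNDLED_MATRICES = ("trna_pair", "small_pair", "medium_pair", "large_pair")


def _data_text(filename: str) -> str:
    return (resources.files("dcjrna") / "data" / filename).read_text()


def load_structure(key: str) -> SecondaryStructure:
    """Bundled example structures in component notation (E. coli tRNA-Leu
    and tRNA-Ala from the genomic tRNA database)."""
    if key not in BUNDLED_STRUCTURES:
        raise KeyError(f"unknown structure {key!r}; have {BUNDLED_STRUCTURES}")
    return parse_component_text(_data_text(f"{key}.txt"))


def load_matrix(key: str) -> SimilarityMatrix:
    """Bundled published component-similarity matrices (CompPSA feature
    measure) for the example and benchmark structure pairs."""
    if key not in BUNDLED_MATRICES:
        raise KeyError(f"unknown matrix {key!r}; have {BUNDLED_MATRICES}")
    return SimilarityMatrix.from_tsv(
        resources.files("dcjrna") / "data" / f"{key}_matrix.tsv"
    )
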