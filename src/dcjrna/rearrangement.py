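"""Genome permutations, adjacency graphs, DCJ distance and sorting.

A genome is a set of chromosomes, each an ordered list of signed genes,
linear or circular.  Every gene has two extremities, tail ``t`` and head
``h``; a genome is fully described by its *adjacencies* (unordered pairs
of consecutive extremities) and *telomeres* (lone extremities at linear
chromosome ends).

The adjacency graph of two genomes over the same genes is a bipartite
multigraph with one vertex per adjacency/telomere and one edge per gene
extremity; it decomposes into cycles and paths, and the double-cut-and-join
(DCJ) distance is

    d = N - (c + p/2)

with N genes, c cycles and p odd-length paths.  A DCJ operation cuts the
genome in at most two places and rejoins the freed ends differently, which
covers inversion, translocation, fission, fusion and - through circular
intermediates - transposition and block interchange.

For structure comparison, matched components become genes of two
two-chromosome permutations (the insertions chromosome on the actual side,
the deletions chromosome on the desired side); the modified sorter then
satisfies only the desired main chromosome, leaving deleted components
wherever the operations drop them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .similarity import Assignment

__all__ = [
    "Extremity",
    "Chromosome",
    "Genome",
    "AdjacencySet",
    "AdjacencyGraphSummary",
    "Scenario",
    "SortArray",
    "GenomeError",
    "build_sort_array",
    "permutations_from_sort_array",
    "adjacencies_from_genome",
    "adjacency_graph",
    "dcj_distance",
    "dcj_sort",
    "dcj_sort_modified",
    "apply_operation",
    "parse_grimm",
    "write_grimm",
]


class GenomeError(ValueError):
    """Invalid genome, adjacency set or DCJ operation."""


# An extremity is (gene, end) with end in {"t", "h"}.
Extremity = tuple[int, str]


def _fmt_ext(e: Extremity) -> str:
    return f"{e[0]} {e[1]}"


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise GenomeError("empty chromosome")
        if any(g == 0 for g in self.genes):
            raise GenomeError("gene 0 is not allowed (signs are meaningful)")


@dataclass(frozen=True)
class Genome:
    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen: set[int] = set()
        for chrom in self.chromosomes:
            for g in chrom.genes:
                if abs(g) in seen:
                    raise GenomeError(f"{self.name}: gene {abs(g)} appears twice")
                seen.add(abs(g))

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(abs(g) for c in self.chromosomes for g in c.genes)


class AdjacencySet:
    """A genome state: adjacencies and telomeres over a fixed gene set.

    Elements are frozensets of one extremity (telomere) or two
    (adjacency).  Insertion order of elements is preserved so that
    scenarios print in a stable, readable order.
    """

    def __init__(self, elements: Iterable[frozenset]):
        self._elements: tuple[frozenset, ...] = tuple(
            frozenset(e) for e in elements
        )
        self._of: dict[Extremity, frozenset] = {}
        for el in self._elements:
            if not 1 <= len(el) <= 2:
                raise GenomeError(f"element must hold 1 or 2 extremities: {el}")
            for ext in el:
                if ext in self._of:
                    raise GenomeError(f"extremity {_fmt_ext(ext)} appears twice")
                self._of[ext] = el
        genes = {e[0] for e in self._of}
        for g in genes:
            for end in ("t", "h"):
                if (g, end) not in self._of:
                    raise GenomeError(f"missing extremity {g} {end}")

    @property
    def elements(self) -> tuple[frozenset, ...]:
        return self._elements

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(e[0] for e in self._of)

    @property
    def adjacencies(self) -> frozenset[frozenset]:
        return frozenset(e for e in self._elements if len(e) == 2)

    @property
    def telomeres(self) -> frozenset[frozenset]:
        return frozenset(e for e in self._elements if len(e) == 1)

    def element_of(self, ext: Extremity) -> frozenset:
        return self._of[ext]

    def __contains__(self, element: frozenset) -> bool:
        return frozenset(element) in set(self._elements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencySet):
            return NotImplemented
        return set(self._elements) == set(other._elements)

    def __hash__(self) -> int:
        return hash(frozenset(self._elements))

    def __len__(self) -> int:
        return len(self._elements)

    def __repr__(self) -> str:
        return f"AdjacencySet({self.render()})"

    def render(self) -> str:
        """Brace notation, e.g. ``{{1 t}, {1 h, 2 t}, {2 h}}``."""
        parts = []
        for el in self._elements:
            inner = ", ".join(_fmt_ext(e) for e in sorted(el))
            parts.append("{" + inner + "}")
        return "{" + ", ".join(parts) + "}"

    def as_strings(self) -> list[str]:
        """Compact strings like ``"1h,2t"`` / ``"6t"`` (JSON-friendly)."""
        return [",".join(f"{g}{end}" for g, end in sorted(el)) for el in self._elements]


def adjacencies_from_genome(g: Genome) -> AdjacencySet:
    """Adjacency/telomere representation of a genome.

    A positive gene contributes tail-then-head along the chromosome, a
    negative gene head-then-tail.  Circular chromosomes join last to first
    and have no telomeres.
    """
    elements: list[frozenset] = []
    for chrom in g.chromosomes:
        ends: list[tuple[Extremity, Extremity]] = []
        for gene in chrom.genes:
            if gene > 0:
                ends.append(((gene, "t"), (gene, "h")))
            else:
                ends.append(((-gene, "h"), (-gene, "t")))
        if chrom.circular:
            for k in range(len(ends)):
                right = ends[k][1]
                left_next = ends[(k + 1) % len(ends)][0]
                elements.append(frozenset({right, left_next}))
        else:
            elements.append(frozenset({ends[0][0]}))
            for k in range(len(ends) - 1):
                elements.append(frozenset({ends[k][1], ends[k + 1][0]}))
            elements.append(frozenset({ends[-1][1]}))
    return AdjacencySet(elements)


@dataclass(frozen=True)
class AdjacencyGraphSummary:
    n_genes: int
    cycles: int
    odd_paths: int
    even_paths: int


def _check_same_genes(a: AdjacencySet, b: AdjacencySet) -> None:
    if a.genes != b.genes:
        diff = sorted(a.genes ^ b.genes)
        raise GenomeError(f"gene sets differ; symmetric difference: {diff}")


def adjacency_graph(a: AdjacencySet, b: AdjacencySet) -> AdjacencyGraphSummary:
    """Cycle/path decomposition of the adjacency graph of two genomes.

    One vertex per element of either genome, one edge per gene extremity.
    """
    _check_same_genes(a, b)
    graph = nx.MultiGraph()
    for side, s in (("A", a), ("B", b)):
        for idx, el in enumerate(s.elements):
            graph.add_node((side, idx), size=len(el))
    index_a = {el: i for i, el in enumerate(a.elements)}
    index_b = {el: i for i, el in enumerate(b.elements)}
    for gene in sorted(a.genes):
        for end in ("t", "h"):
            ext = (gene, end)
            graph.add_edge(
                ("A", index_a[a.element_of(ext)]),
                ("B", index_b[b.element_of(ext)]),
            )
    cycles = odd = even = 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        n_edges = sub.number_of_edges()
        if n_edges == sub.number_of_nodes():
            cycles += 1
        elif n_edges % 2 == 1:
            odd += 1
        else:
            even += 1
    return AdjacencyGraphSummary(
        n_genes=len(a.genes), cycles=cycles, odd_paths=odd, even_paths=even
    )


def dcj_distance(a: AdjacencySet, b: AdjacencySet) -> int:
    """Minimum number of DCJ operations: N - (c + p/2)."""
    s = adjacency_graph(a, b)
    twice = 2 * s.n_genes - (2 * s.cycles + s.odd_paths)
    assert twice % 2 == 0, "odd paths must come in pairs"
    return twice // 2


@dataclass(frozen=True)
class Scenario:
    """Ordered genome states, consecutive ones a single DCJ apart."""

    states: tuple[AdjacencySet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not self.states:
            raise GenomeError("a scenario needs at least one state")

    @property
    def n_operations(self) -> int:
        return len(self.states) - 1

    @property
    def final(self) -> AdjacencySet:
        return self.states[-1]

    def render(self) -> str:
        return "{" + ",\n".join(s.render() for s in self.states) + "}"

    def to_jsonable(self) -> list[list[str]]:
        return [s.as_strings() for s in self.states]


def apply_operation(
    state: AdjacencySet,
    cuts: Sequence[frozenset],
    joins: Sequence[frozenset],
) -> AdjacencySet:
    """Apply one DCJ operation: remove ``cuts`` (at most two existing
    elements), re-add ``joins`` built from exactly the freed extremities."""
    cuts = [frozenset(c) for c in cuts]
    joins = [frozenset(j) for j in joins]
    if len(cuts) > 2:
        raise GenomeError("a DCJ operation cuts at most two elements")
    existing = set(state.elements)
    freed: set[Extremity] = set()
    for c in cuts:
        if c not in existing:
            raise GenomeError(f"cannot cut absent element {set(c)}")
        freed |= set(c)
    joined: set[Extremity] = set()
    for j in joins:
        if not 1 <= len(j) <= 2:
            raise GenomeError("joins must hold 1 or 2 extremities")
        joined |= set(j)
    if joined != freed:
        raise GenomeError(
            "joins must use exactly the freed extremities "
            f"(freed {sorted(freed)}, joined {sorted(joined)})"
        )
    new_elements = [el for el in state.elements if el not in cuts] + list(joins)
    return AdjacencySet(new_elements)


def _sort_steps(
    start: AdjacencySet, target_elements: Sequence[frozenset]
) -> list[AdjacencySet]:
    """Greedy optimal sorting toward the given target elements.

    Target adjacencies are satisfied first, in the order given, then
    target telomeres; each unsatisfied element costs exactly one DCJ.
    """
    states = [start]
    cur = start
    for tgt in [e for e in target_elements if len(e) == 2]:
        p, q = sorted(tgt)
        u = cur.element_of(p)
        v = cur.element_of(q)
        if u == v:
            continue  # already the adjacency {p, q}
        rest = (u | v) - tgt
        joins = [tgt] + ([frozenset(rest)] if rest else [])
        cur = apply_operation(cur, [u, v], joins)
        states.append(cur)
    for tgt in [e for e in target_elements if len(e) == 1]:
        (p,) = tgt
        u = cur.element_of(p)
        if len(u) == 1:
            continue
        cur = apply_operation(cur, [u], [tgt, u - tgt])
        states.append(cur)
    return states


def dcj_sort(current: AdjacencySet, target: AdjacencySet) -> Scenario:
    """An optimal sorting scenario from ``current`` to ``target``.

    The number of operations always equals ``dcj_distance`` and the final
    state equals the target exactly.
    """
    _check_same_genes(current, target)
    states = _sort_steps(current, target.elements)
    assert states[-1] == target
    return Scenario(states=tuple(states))


def dcj_sort_modified(actual: Genome, desired: Genome) -> Scenario:
    """Sort the actual permutation to realise the desired main chromosome.

    Only chromosome 1 of ``desired`` is targeted; the deletions chromosome
    is left unsorted, so extremities of deleted genes end wherever the
    operations leave them (telomeres or excised circular pieces).
    """
    start = adjacencies_from_genome(actual)
    desired_set = adjacencies_from_genome(desired)
    _check_same_genes(start, desired_set)
    if desired.chromosomes:
        chr1 = Genome(name=desired.name, chromosomes=(desired.chromosomes[0],))
        target_elements = adjacencies_from_genome(chr1).elements
    else:
        target_elements = ()
    states = _sort_steps(start, target_elements)
    final = states[-1]
    assert all(el in final for el in target_elements)
    return Scenario(states=tuple(states))


# --- SortArray: permutation encoding of an assignment ---------------------


@dataclass(frozen=True)
class SortArray:
    """Three-row encoding of a component assignment as gene labels.

    Matched components of the desired structure carry their actual-side
    partner's index; an inserted desired-side component ``i`` carries the
    label ``i + N`` with N the actual structure's component count.
    """

    actual_count: int
    desired_row: tuple[int, ...]
    deleted_row: tuple[int, ...]
    inserted_row: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "desired_row", tuple(self.desired_row))
        object.__setattr__(self, "deleted_row", tuple(self.deleted_row))
        object.__setattr__(self, "inserted_row", tuple(self.inserted_row))
        if set(self.deleted_row) & set(self.desired_row):
            raise GenomeError("deleted labels cannot appear in the desired row")
        if not set(self.inserted_row) <= set(self.desired_row):
            raise GenomeError("inserted labels must appear in the desired row")


def build_sort_array(asg: Assignment, n_a: int, n_b: int) -> SortArray:
    """Relabel an assignment as genes (see :class:`SortArray`).

    ``n_a``/``n_b`` are the component counts of the actual and desired
    structures.
    """
    if asg.n_a != n_a or asg.n_b != n_b:
        raise GenomeError(
            f"assignment covers {asg.n_a}x{asg.n_b} components, "
            f"structures have {n_a}x{n_b}"
        )
    label_of_b: dict[int, int] = {}
    for ai, bi, _ in asg.matches:
        if not (1 <= ai <= n_a and 1 <= bi <= n_b):
            raise GenomeError(f"match ({ai}, {bi}) references unknown components")
        label_of_b[bi] = ai
    for bi in asg.inserted:
        label_of_b[bi] = bi + n_a
    return SortArray(
        actual_count=n_a,
        desired_row=tuple(label_of_b[bi] for bi in range(1, n_b + 1)),
        deleted_row=tuple(asg.deleted),
        inserted_row=tuple(bi + n_a for bi in asg.inserted),
    )


def permutations_from_sort_array(sa: SortArray) -> tuple[Genome, Genome]:
    """Two-chromosome permutations for the DCJ step.

    Actual genome: chromosome 1 is the identity 1..N, chromosome 2 the
    inserted labels.  Desired genome: chromosome 1 is the desired row,
    chromosome 2 the deleted labels.  Empty chromosomes are omitted; all
    genes are positively oriented.
    """
    actual_chroms = []
    if sa.actual_count:
        actual_chroms.append(Chromosome(tuple(range(1, sa.actual_count + 1))))
    if sa.inserted_row:
        actual_chroms.append(Chromosome(sa.inserted_row))
    desired_chroms = [Chromosome(sa.desired_row)] if sa.desired_row else []
    if sa.deleted_row:
        desired_chroms.append(Chromosome(sa.deleted_row))
    return (
        Genome(name="actual", chromosomes=tuple(actual_chroms)),
        Genome(name="desired", chromosomes=tuple(desired_chroms)),
    )


# --- GRIMM-style genome files ---------------------------------------------


def parse_grimm(text: str, default_name: str = "genome") -> Genome:
    """Parse one GRIMM-style genome: ``>name`` then one line per
    chromosome of signed integers ending in ``$`` (linear) or ``@``
    (circular)."""
    name = default_name
    chroms: list[Chromosome] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].strip() or default_name
            continue
        if line.endswith("$"):
            circular = False
        elif line.endswith("@"):
            circular = True
        else:
            raise GenomeError(
                f"chromosome line must end with '$' or '@': {line!r}"
            )
        body = line[:-1].split()
        try:
            genes = tuple(int(tok) for tok in body)
        except ValueError as exc:
            raise GenomeError(f"bad gene token in {line!r}") from exc
        chroms.append(Chromosome(genes=genes, circular=circular))
    if not chroms:
        raise GenomeError("no chromosomes found")
    return Genome(name=name, chromosomes=tuple(chroms))


def write_grimm(g: Genome) -> str:
    lines = [f">{g.name}"]
    for chrom in g.chromosomes:
        mark = "@" if chrom.circular else "$"
        lines.append(" ".join(str(x) for x in chrom.genes) + f" {mark}")
    return "\n".join(lines) + "\n"
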