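"""Adjacency sets, adjacency graphs, DCJ distance and sorting."""

import pytest

from dcjrna import fixtures as fx
from dcjrna.rearrangement import (
    AdjacencySet,
    Chromosome,
    Genome,
    GenomeError,
    SortArray,
    adjacencies_from_genome,
    adjacency_graph,
    apply_operation,
    build_sort_array,
    dcj_distance,
    dcj_sort,
    dcj_sort_modified,
    parse_grimm,
    permutations_from_sort_array,
    write_grimm,
)
from dcjrna.similarity import Assignment, greedy_assign, position_matrix


def linear(*genes):
    return Genome(name="g", chromosomes=(Chromosome(tuple(genes)),))


def adjset(*elements):
    return AdjacencySet([frozenset(e) for e in elements])


T = lambda g: (g, "t")
H = lambda g: (g, "h")


# --- worked-example and benchmark objects ---------------------------------

WORKED_ASSIGNMENT = Assignment(
    matches=((3, 3, 1.0), (5, 4, 1.0), (2, 2, 0.83)), deleted=(1, 4), inserted=(1,)
)
SMALL_ASSIGNMENT = Assignment(
    matches=((1, 1, 0.97), (3, 4, 0.95), (2, 2, 0.74)), deleted=(), inserted=(3,)
)


class TestSortArray:
    def test_worked_example_rows(self):
        sa = build_sort_array(WORKED_ASSIGNMENT, 5, 4)
        assert sa.desired_row == (6, 2, 3, 5)
        assert sa.deleted_row == (1, 4)
        assert sa.inserted_row == (6,)
        assert sa.actual_count == 5

    def test_small_pair_rows(self):
        sa = build_sort_array(SMALL_ASSIGNMENT, 3, 4)
        assert sa.desired_row == (1, 2, 6, 3)
        assert sa.deleted_row == ()
        assert sa.inserted_row == (6,)

    def test_identity_assignment(self):
        asg = Assignment(
            matches=tuple((i, i, 1.0) for i in range(1, 4)), deleted=(), inserted=()
        )
        sa = build_sort_array(asg, 3, 3)
        assert sa.desired_row == (1, 2, 3)
        assert sa.deleted_row == sa.inserted_row == ()

    def test_inconsistent_assignment_rejected(self):
        with pytest.raises(GenomeError):
            build_sort_array(WORKED_ASSIGNMENT, 4, 4)

    def test_deleted_label_in_desired_row_rejected(self):
        with pytest.raises(GenomeError):
            SortArray(3, desired_row=(1, 2), deleted_row=(1,), inserted_row=())


class TestPermutations:
    def test_worked_example(self):
        ga, gd = permutations_from_sort_array(build_sort_array(WORKED_ASSIGNMENT, 5, 4))
        assert [c.genes for c in ga.chromosomes] == [(1, 2, 3, 4, 5), (6,)]
        assert [c.genes for c in gd.chromosomes] == [(6, 2, 3, 5), (1, 4)]

    def test_small_pair(self):
        ga, gd = permutations_from_sort_array(build_sort_array(SMALL_ASSIGNMENT, 3, 4))
        assert [c.genes for c in ga.chromosomes] == [(1, 2, 3), (6,)]
        assert [c.genes for c in gd.chromosomes] == [(1, 2, 6, 3)]

    def test_identity(self):
        asg = Assignment(
            matches=tuple((i, i, 1.0) for i in range(1, 5)), deleted=(), inserted=()
        )
        ga, gd = permutations_from_sort_array(build_sort_array(asg, 4, 4))
        assert [c.genes for c in ga.chromosomes] == [(1, 2, 3, 4)]
        assert [c.genes for c in gd.chromosomes] == [(1, 2, 3, 4)]


class TestAdjacencies:
    def test_worked_example_actual(self):
        ga, _ = permutations_from_sort_array(build_sort_array(WORKED_ASSIGNMENT, 5, 4))
        s = adjacencies_from_genome(ga)
        assert s == adjset(
            [T(1)], [H(1), T(2)], [H(2), T(3)], [H(3), T(4)], [H(4), T(5)],
            [H(5)], [T(6)], [H(6)],
        )

    def test_two_gene_linear(self):
        s = adjacencies_from_genome(linear(1, 2))
        assert s == adjset([T(1)], [H(1), T(2)], [H(2)])

    def test_negative_gene_swaps_ends(self):
        s = adjacencies_from_genome(linear(1, -2))
        assert s == adjset([T(1)], [H(1), H(2)], [T(2)])

    def test_circular_singleton(self):
        g = Genome(name="c", chromosomes=(Chromosome((1,), circular=True),))
        s = adjacencies_from_genome(g)
        assert s == adjset([H(1), T(1)])
        assert not s.telomeres

    def test_duplicate_gene_rejected(self):
        with pytest.raises(GenomeError):
            Genome(name="bad", chromosomes=(Chromosome((1, 2, 1)),))


class TestAdjacencyGraph:
    def test_identity_decomposition(self):
        for n in (2, 4, 6):
            s = adjacencies_from_genome(linear(*range(1, n + 1)))
            summary = adjacency_graph(s, s)
            assert summary.cycles == n - 1
            assert summary.odd_paths == 2
            assert summary.even_paths == 0

    def test_small_pair_decomposition(self):
        ga, gd = permutations_from_sort_array(build_sort_array(SMALL_ASSIGNMENT, 3, 4))
        summary = adjacency_graph(
            adjacencies_from_genome(ga), adjacencies_from_genome(gd)
        )
        assert (summary.cycles, summary.odd_paths) == (1, 2)
        assert summary.odd_paths % 2 == 0

    def test_gene_set_mismatch_reported(self):
        with pytest.raises(GenomeError, match="symmetric difference"):
            adjacency_graph(
                adjacencies_from_genome(linear(1, 2)),
                adjacencies_from_genome(linear(1, 3)),
            )


class TestDistance:
    def test_self_distance_zero(self):
        s = adjacencies_from_genome(linear(3, 1, 2))
        assert dcj_distance(s, s) == 0

    def test_small_pair_distance_two(self):
        ga, gd = permutations_from_sort_array(build_sort_array(SMALL_ASSIGNMENT, 3, 4))
        assert dcj_distance(
            adjacencies_from_genome(ga), adjacencies_from_genome(gd)
        ) == 2

    def test_circularization_is_one_step(self):
        lin = adjacencies_from_genome(linear(1))
        circ = adjacencies_from_genome(
            Genome(name="c", chromosomes=(Chromosome((1,), circular=True),))
        )
        assert dcj_distance(lin, circ) == 1
        assert dcj_distance(lin, circ) == fx.bfs_dcj_distance(lin, circ)


class TestSorting:
    def test_identical_sets_empty_scenario(self):
        s = adjacencies_from_genome(linear(1, 2, 3))
        sc = dcj_sort(s, s)
        assert sc.n_operations == 0 and sc.final == s

    def test_small_pair_scenario_reaches_printed_target(self):
        ga, gd = permutations_from_sort_array(build_sort_array(SMALL_ASSIGNMENT, 3, 4))
        target = adjacencies_from_genome(gd)
        sc = dcj_sort(adjacencies_from_genome(ga), target)
        assert sc.n_operations == 2
        assert sc.final == adjset(
            [T(1)], [H(1), T(2)], [H(2), T(6)], [H(6), T(3)], [H(3)]
        )

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bfs_minimum_on_random_small_genomes(self, seed):
        states = fx.enumerate_adjacency_sets(3)
        import random

        r = random.Random(seed)
        a, b = r.choice(states), r.choice(states)
        sc = dcj_sort(a, b)
        assert sc.n_operations == dcj_distance(a, b) == fx.bfs_dcj_distance(a, b)
        assert sc.final == b

    def test_scenario_replays_via_apply_operation(self):
        ga, gd = permutations_from_sort_array(build_sort_array(WORKED_ASSIGNMENT, 5, 4))
        sc = dcj_sort_modified(ga, gd)
        state = sc.states[0]
        for nxt in sc.states[1:]:
            cuts = [el for el in state.elements if el not in set(nxt.elements)]
            joins = [el for el in nxt.elements if el not in set(state.elements)]
            state = apply_operation(state, cuts, joins)
            assert state == nxt


class TestModifiedSorting:
    def test_worked_example_final_state(self):
        """Deleted components drift: gene 4 is excised as a circular
        singleton and gene 1 ends as two telomeres."""
        ga, gd = permutations_from_sort_array(build_sort_array(WORKED_ASSIGNMENT, 5, 4))
        sc = dcj_sort_modified(ga, gd)
        assert sc.n_operations == 2
        assert sc.final == adjset(
            [T(6)], [H(6), T(2)], [H(1)], [T(1)], [H(2), T(3)],
            [H(3), T(5)], [H(4), T(4)], [H(5)],
        )

    def test_target_elements_all_present(self):
        ga, gd = permutations_from_sort_array(build_sort_array(WORKED_ASSIGNMENT, 5, 4))
        sc = dcj_sort_modified(ga, gd)
        for el in (
            frozenset({T(6)}), frozenset({H(6), T(2)}), frozenset({H(2), T(3)}),
            frozenset({H(3), T(5)}), frozenset({H(5)}),
        ):
            assert el in sc.final

    def test_reduces_to_full_sort_without_deletions(self):
        ga, gd = permutations_from_sort_array(build_sort_array(SMALL_ASSIGNMENT, 3, 4))
        modified = dcj_sort_modified(ga, gd)
        full = dcj_sort(adjacencies_from_genome(ga), adjacencies_from_genome(gd))
        assert modified.n_operations == full.n_operations
        assert modified.final == full.final

    def test_never_exceeds_full_distance(self, trna_pair):
        from dcjrna.similarity import build_matrix

        A, B = trna_pair
        m = build_matrix(A, B)
        asg = greedy_assign(m, position_matrix(A, B), epsilon=0.6)
        ga, gd = permutations_from_sort_array(build_sort_array(asg, len(A), len(B)))
        sc = dcj_sort_modified(ga, gd)
        full = dcj_distance(adjacencies_from_genome(ga), adjacencies_from_genome(gd))
        assert sc.n_operations <= full


class TestApplyOperation:
    def test_circular_excision(self):
        s = adjset([T(3)], [H(3), T(4)], [H(4), T(5)], [H(5)])
        out = apply_operation(
            s,
            cuts=[frozenset({H(3), T(4)}), frozenset({H(4), T(5)})],
            joins=[frozenset({H(3), T(5)}), frozenset({H(4), T(4)})],
        )
        assert frozenset({H(4), T(4)}) in out

    def test_identity_operation(self):
        s = adjacencies_from_genome(linear(1, 2))
        assert apply_operation(s, [], []) == s

    def test_join_must_use_freed_extremities(self):
        s = adjacencies_from_genome(linear(1, 2))
        with pytest.raises(GenomeError):
            apply_operation(
                s, cuts=[frozenset({T(1)})], joins=[frozenset({T(1), H(2)})]
            )

    def test_cut_of_absent_element_rejected(self):
        s = adjacencies_from_genome(linear(1, 2))
        with pytest.raises(GenomeError):
            apply_operation(s, cuts=[frozenset({T(1), T(2)})], joins=[])


class TestGrimm:
    def test_round_trip(self):
        g = Genome(
            name="x",
            chromosomes=(Chromosome((1, -3, 2)), Chromosome((4,), circular=True)),
        )
        assert parse_grimm(write_grimm(g)) == g

    def test_parse_errors(self):
        with pytest.raises(GenomeError):
            parse_grimm(">x\n1 2 3\n")  # missing terminator
        with pytest.raises(GenomeError):
            parse_grimm(">x\n1 two $\n")
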