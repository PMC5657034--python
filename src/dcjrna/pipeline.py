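"""End-to-end comparison pipeline and its serialisable report.

``run_compare`` executes the three stages in order: (1) greedy threshold
matching of helix components on a similarity matrix (computed from the
two-feature measure, or supplied externally as TSV); (2) relabelling of
the matched/inserted/deleted components into two two-chromosome
permutations; (3) DCJ sorting of the actual permutation toward the
desired main chromosome, yielding the operation count and an explicit
scenario.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import rearrangement as rea
from . import similarity as sim
from .structures import SecondaryStructure

__all__ = ["ComparisonReport", "run_compare", "render_desired_structure"]


@dataclass(frozen=True)
class ComparisonReport:
    """Everything one comparison produced, JSON round-trippable."""

    name_a: str
    name_b: str
    weights: sim.FeatureWeights
    matrix: sim.SimilarityMatrix
    matrix_supplied: bool
    assignment: sim.Assignment
    sort_array: rea.SortArray
    genome_actual: rea.Genome
    genome_desired: rea.Genome
    adjacencies_actual: list[str]
    adjacencies_desired: list[str]
    n_operations: int
    scenario: list[list[str]]
    scenario_text: str
    similarity_before: float
    similarity_after: float

    def to_dict(self) -> dict:
        return {
            "name_a": self.name_a,
            "name_b": self.name_b,
            "weights": asdict(self.weights),
            "matrix": {
                "rows": list(self.matrix.row_labels),
                "cols": list(self.matrix.col_labels),
                "values": self.matrix.values.tolist(),
            },
            "matrix_supplied": self.matrix_supplied,
            "assignment": {
                "matches": [list(m) for m in self.assignment.matches],
                "deleted": list(self.assignment.deleted),
                "inserted": list(self.assignment.inserted),
            },
            "sort_array": {
                "actual_count": self.sort_array.actual_count,
                "desired_row": list(self.sort_array.desired_row),
                "deleted_row": list(self.sort_array.deleted_row),
                "inserted_row": list(self.sort_array.inserted_row),
            },
            "genome_actual": rea.write_grimm(self.genome_actual),
            "genome_desired": rea.write_grimm(self.genome_desired),
            "adjacencies_actual": self.adjacencies_actual,
            "adjacencies_desired": self.adjacencies_desired,
            "n_operations": self.n_operations,
            "scenario": self.scenario,
            "scenario_text": self.scenario_text,
            "similarity_before": self.similarity_before,
            "similarity_after": self.similarity_after,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            name_a=d["name_a"],
            name_b=d["name_b"],
            weights=sim.FeatureWeights(**d["weights"]),
            matrix=sim.SimilarityMatrix(
                row_labels=tuple(d["matrix"]["rows"]),
                col_labels=tuple(d["matrix"]["cols"]),
                values=np.array(d["matrix"]["values"], dtype=float).reshape(
                    len(d["matrix"]["rows"]), len(d["matrix"]["cols"])
                ),
            ),
            matrix_supplied=d["matrix_supplied"],
            assignment=sim.Assignment(
                matches=tuple(tuple(m) for m in d["assignment"]["matches"]),
                deleted=tuple(d["assignment"]["deleted"]),
                inserted=tuple(d["assignment"]["inserted"]),
            ),
            sort_array=rea.SortArray(
                actual_count=d["sort_array"]["actual_count"],
                desired_row=tuple(d["sort_array"]["desired_row"]),
                deleted_row=tuple(d["sort_array"]["deleted_row"]),
                inserted_row=tuple(d["sort_array"]["inserted_row"]),
            ),
            genome_actual=rea.parse_grimm(d["genome_actual"]),
            genome_desired=rea.parse_grimm(d["genome_desired"]),
            adjacencies_actual=list(d["adjacencies_actual"]),
            adjacencies_desired=list(d["adjacencies_desired"]),
            n_operations=d["n_operations"],
            scenario=[list(s) for s in d["scenario"]],
            scenario_text=d["scenario_text"],
            similarity_before=d["similarity_before"],
            similarity_after=d["similarity_after"],
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(text))


def render_desired_structure(
    sort_array: rea.SortArray, B: SecondaryStructure
) -> SecondaryStructure:
    """Structure realised by the sorted main chromosome.

    After sorting, the actual genome's main chromosome carries the desired
    component order; each of its genes corresponds to one component of the
    desired structure and is rendered at that component's coordinates.
    """
    tuples = [
        (c.ob, c.cb, c.stem_len)
        for label, c in zip(sort_array.desired_row, B.components)
    ]
    return SecondaryStructure.from_tuples(f"{B.name}_sorted", B.length, tuples)


def run_compare(
    A: SecondaryStructure,
    B: SecondaryStructure,
    weights: sim.FeatureWeights = sim.FeatureWeights(),
    matrix: Optional[sim.SimilarityMatrix] = None,
) -> ComparisonReport:
    """Compare two structures and report the full rearrangement account.

    When ``matrix`` is given it replaces the computed two-feature
    similarity (its shape must be ``len(A) x len(B)``); position
    similarities for tie-breaking always come from the structures.
    """
    supplied = matrix is not None
    if matrix is None:
        matrix = sim.build_matrix(A, B, weights)
    elif matrix.shape != (len(A), len(B)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not fit structures "
            f"({len(A)} x {len(B)} components)"
        )
    positions = sim.position_matrix(A, B) if len(A) and len(B) else None
    assignment = sim.greedy_assign(matrix, positions, epsilon=weights.epsilon)
    sort_array = rea.build_sort_array(assignment, len(A), len(B))
    genome_actual, genome_desired = rea.permutations_from_sort_array(sort_array)
    adj_actual = rea.adjacencies_from_genome(genome_actual)
    adj_desired = rea.adjacencies_from_genome(genome_desired)
    scenario = rea.dcj_sort_modified(genome_actual, genome_desired)
    before = sim.score_percentage(A, B, weights)
    after = sim.score_percentage(render_desired_structure(sort_array, B), B, weights)
    return ComparisonReport(
        name_a=A.name,
        name_b=B.name,
        weights=weights,
        matrix=matrix,
        matrix_supplied=supplied,
        assignment=assignment,
        sort_array=sort_array,
        genome_actual=genome_actual,
        genome_desired=genome_desired,
        adjacencies_actual=adj_actual.as_strings(),
        adjacencies_desired=adj_desired.as_strings(),
        n_operations=scenario.n_operations,
        scenario=scenario.to_jsonable(),
        scenario_text=scenario.render(),
        similarity_before=before,
        similarity_after=after,
    )
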