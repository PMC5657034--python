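# Methods

## Structure model

A secondary structure is a total length plus an ordered list of
components. A component is one maximal helix — a run of stacked base
pairs with no interruption on either strand — stored as `(ob, cb,
stem_len)` with 1-based coordinates: `ob` is the first base of the
opening strand, `cb` the first base of the closing strand, and spans are
closed intervals. The component's *full length* is `cb + stem_len − ob`,
the base count from its first to its last base; with this convention two
identical printed tuples always score 1. Structures must be non-crossing:
a nested helix lies entirely inside the enclosing helix's loop region
(pseudoknots are out of scope). Intermolecular (INTERM) records of
interacting patterns are parsed and carried through untouched; only
intramolecular components are matched and rearranged.

Dot-bracket input is decomposed by stack matching; a helix is split at
*any* interruption of stacking (bulge or internal loop on either strand).
This convention gives tRNA cloverleafs the expected four arms plus
acceptor stem and makes the decomposition canonical, so writing and
re-parsing a structure is the identity.

## Component similarity and matching

Two features drive matching, each a min/max ratio in [0, 1]: full length
and stem length. The default score is their product; a weighted
arithmetic mean (`w_cl`, `w_sl`) is available as an alternative combiner.
Relative start position, `1 − |ob_a/L_a − ob_b/L_b|`, is deliberately
*not* part of the score: it only breaks ties between entries that are
equal at the matcher's precision (1e-9), followed by the lowest
(row, column) pair so results are deterministic even without coordinate
information. Matching is greedy on the largest remaining entry and a pair
is accepted when its score is ≥ ε (inclusive; no shipped case sits
exactly at the threshold). Defaults: ε = 0.6, `w_cl` = `w_sl` = 1,
`w_p` = 0, product combiner — suited to structurally similar molecules;
ε = 0.8 is the recommended preset for dissimilar ones.

The exact feature equations behind published CompPSA matrices are not
reimplemented; such matrices are accepted as labelled TSV and consumed
directly by the matcher, which is how the bundled benchmark pairs are
reproduced number-for-number.

The before/after similarity percentage comes from a Needleman–Wunsch
alignment over the ordered component lists with gap score 0 and match
score `d1` (plus a `w_p`-weighted position term when `w_p` > 0; with the
product combiner the position similarity multiplies the score),
normalised by the larger self-alignment. Gap score 0 means the optimum is
simply the best order-preserving pairing; self-comparison is always 100%.
The "after" percentage scores the structure realised by the sorted main
chromosome — each matched or inserted component rendered at its desired
coordinates — against the desired structure, so it reaches 100 whenever
sorting completes; it is reported for symmetry with the "before" value.

## Permutation encoding

The matching becomes a `SortArray`: the desired structure's components in
order (matched ones labelled by their actual-side partner, insertions by
`i + N`), plus the deletion and insertion rows. Genes are unsigned
(helices carry no orientation here) but the DCJ layer supports signs, so
the rearrangement core is general. Actual genome: linear chromosome
1..N plus a linear insertions chromosome; desired genome: the desired row
plus a deletions chromosome. Empty chromosomes are omitted.

## DCJ distance and sorting

Genomes are converted to adjacency/telomere sets; the adjacency graph
(one vertex per adjacency or telomere, one edge per gene extremity,
decomposed with networkx) yields the closed-form distance
`N − (c + p/2)`. Odd paths necessarily come in pairs, so the distance is
integral. Sorting follows the standard greedy adjacency-graph algorithm:
each target adjacency `{p, q}` not yet present is created by cutting the
at most two current elements containing `p` and `q` and joining the
leftovers into one element (or leaving a telomere when only one extremity
is freed); target telomeres are resolved afterwards by single cuts.
Target adjacencies are processed in target-chromosome order, which makes
scenarios deterministic. Each step satisfies one target element, so the
scenario length equals the distance.

The modified sorter used by the pipeline restricts the target to the
desired *main* chromosome: deleted components need no final arrangement,
so their extremities are left wherever the operations drop them —
commonly as fresh telomeres or, when an operation frees both extremities
of one gene, as a circular singleton. Its operation count never exceeds
the full two-chromosome distance.

Correctness is anchored by an independent breadth-first-search oracle
over raw adjacency-set states: the closed-form distance equals the BFS
minimum on an exhaustive sweep of all genome-state pairs over ≤ 3 genes
(2, 10 and 76 states for 1–3 genes) and on 500 seeded random 4-gene
pairs, and every emitted scenario replays exactly through the primitive
cut/join operation with extremity conservation checked at every state.

## Synthetic data

The generator places exactly `n` helices into a backbone of given length
by seeded recursive interval splitting: each helix gets a random leading
gap, span, stem length and a random share of the remaining helices nested
inside its loop versus laid out after it. Defaults `min_stem` = 2 base
pairs and `min_loop` = 3 unpaired bases reflect the shortest sterically
plausible hairpin. Occupied loops reserve one spare base so a nested
helix never stacks seamlessly onto its parent — generated structures are
always in canonical (maximal-helix) form and survive dot-bracket round
trips. Test pairs are built by perturbing a generated structure
(component deletion and insertion, sibling-block swaps, stem resizing)
and by side-by-side duplication, which doubles length and component
count the way the scalability series is constructed.

What the generator does not emulate: sequence content and thermodynamic
plausibility, pseudoknots, interacting (multi-molecule) patterns, and the
size distribution of any particular RNA family. Passing tests therefore
demonstrate algorithmic correctness on valid component arrangements, not
biological realism of the inputs.

## Problem sizes and numerical choices

The property suites run the pipeline on 200 seeded random pairs of 3–7
component structures and the oracle sweep on ≤ 4 genes; these sizes cover
every code path (insertions, deletions, reordering, circular excision)
while keeping the whole suite a few seconds long. Scores are plain
floats; the only tolerance in the algorithmic path is the 1e-9 tie window
in the greedy matcher, which groups exact ties from printed
two-decimal matrices without ever merging genuinely different scores.
Degenerate inputs are defined, not errors: empty structures give empty
matrices, zero-component comparisons report zero operations, and two
empty structures are 100% similar.

## Known limitations

- Pseudoknotted and interacting structures are rejected or carried
  opaquely; only nested intramolecular helices are rearranged.
- The greedy matcher is order-optimal locally, not a maximum-weight
  bipartite matching; this is intentional (it is the method being
  implemented) but can differ from the global optimum on adversarial
  matrices.
- The built-in two-feature similarity is a documented stand-in for richer
  feature measures; published matrices should be supplied when exact
  reproduction of their matchings is required.
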