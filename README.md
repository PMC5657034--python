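# dcjrna

Compare two RNA secondary structures by rearrangement of their helices.

Sequence-level comparison misses the fact that two RNAs with very
different sequences can fold into the same shape and do the same job.
`dcjrna` works on the shape directly: each structure is reduced to its
ordered list of *components* (maximal helices, each recorded as the start
of its opening strand `ob`, the start of its closing strand `cb`, and its
stem length), similar components of the two structures are matched, and
the reordering that turns one arrangement into the other is expressed as
a minimum-length sequence of **double-cut-and-join (DCJ)** operations —
the same operation that unifies inversion, translocation, fission, fusion
and block interchange in genome rearrangement studies. The output is both
a distance (how many operations) and an explicit evolutionary scenario
(which cuts and joins, in which order). It is aimed at people studying
structural evolution of ncRNAs who want a rearrangement-based alternative
to tree alignment or base-pair distances.

## Method

1. **Match components.** Components `a_i`, `b_j` are scored by
   `d1 = min(ℓ_a,ℓ_b)/max(ℓ_a,ℓ_b) · min(s_a,s_b)/max(s_a,s_b)`
   (full-length ratio times stem-length ratio, each in [0,1]).
   A greedy pass repeatedly takes the largest matrix entry; pairs scoring
   at least the threshold ε are fixed (ties broken by closest relative
   position), leftover rows are deletions and leftover columns
   insertions. A published similarity matrix (e.g. from the CompPSA
   measure) can be supplied as TSV instead of the built-in `d1`.
2. **Encode as permutations.** Matched components of the second
   (desired) structure take their partner's index; an inserted component
   `i` takes `i + N` (N = components in the first structure). This yields
   two two-chromosome genomes: actual = (1..N | insertions), desired =
   (desired order | deletions).
3. **Sort by DCJ.** Both genomes become adjacency/telomere sets; the DCJ
   distance is `d = N_g − (c + p/2)` from the cycles `c` and odd paths `p`
   of their adjacency graph, and a sorting scenario of exactly that length
   is emitted. The modified sorter targets only the desired main
   chromosome, so deleted components simply drift (often excised as
   circular singletons).

An order-preserving Needleman–Wunsch alignment of the component lists
reports an overall similarity percentage before and after sorting.

## Worked example

The bundled pair is E. coli tRNA-Leu (`A`, 85 nt, 5 helices) vs tRNA-Ala
(`B`, 76 nt, 4 helices), with its published component-similarity matrix:

```sh
python -c "
from dcjrna import fixtures as fx
A = fx.load_structure('trna_leu'); B = fx.load_structure('trna_ala')
open('A.txt','w').write(A.to_json()); open('B.txt','w').write(B.to_json())
fx.load_matrix('trna_pair').to_tsv('matrix.tsv')"
dcjrna compare A.txt B.txt --matrix matrix.tsv --epsilon 0.5
```

prints

```
structures:    A (5 components) vs B (4 components)
matches:       [(3, 3), (5, 4), (2, 2)]
deleted (A):   [1, 4]
inserted (B):  [1]
desired row:   [6, 2, 3, 5]
operations:    2
similarity:    71.9% before, 100.0% after
scenario:
{{{1 t}, {1 h, 2 t}, {2 h, 3 t}, {3 h, 4 t}, {4 h, 5 t}, {5 h}, {6 t}, {6 h}},
{{1 t}, {2 h, 3 t}, {3 h, 4 t}, {4 h, 5 t}, {5 h}, {6 t}, {2 t, 6 h}, {1 h}},
{{1 t}, {2 h, 3 t}, {5 h}, {6 t}, {2 t, 6 h}, {1 h}, {3 h, 5 t}, {4 h, 4 t}}}
```

Reading: helices a3/b3, a5/b4 and a2/b2 match; a1 and a4 have no
counterpart above ε = 0.5 and are deleted, while b1 (relabelled gene 6)
is inserted. Two DCJ operations turn the actual arrangement into the
desired one: the first attaches gene 6 where the acceptor-stem helix used
to sit (freeing `1h` as a telomere), the second excises gene 4 as a
circular singleton (`{4 h, 4 t}`) while joining `3h` to `5t`. Deleted
genes are not sorted further.

Two other subcommands expose the pieces: `dcjrna distance a.grimm b.grimm
[--scenario]` for the bare DCJ core on GRIMM-style permutation files, and
`dcjrna simulate --seed N --components K --length L [--duplicate]
[--perturb delete:2]` for seeded synthetic structures.

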