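# triphy

Perfect phylogeny decision and construction for character matrices with at
most three states per character, built on minimal-triangulation theory:
legal minimal separators of the partition intersection graph are generated
directly from the matrix via proper clusters, a maximal pairwise parallel
family is saturated into a proper minimal triangulation, and a maximum
cardinality search clique tree of the result is read off as the phylogeny.

## What is in here

| module | role |
| --- | --- |
| `triphy.matrix_io` | read/write/canonicalize matrices (CSV, TSV, digit-PHYLIP); packaged fixtures F1–F5 |
| `triphy.partition_graph` | colored partition intersection graph, pairwise cycle screen, forced chords / augmented graph |
| `triphy.separators` | proper clusters, splitting vectors, legal minimal separators, S-partitions, crossing relations |
| `triphy.triangulation` | greedy parallel family, saturation, MCS clique tree, phylogeny assembly + verification |
| `triphy.oracles` | brute-force references: subset-scan and expansion-based separator enumeration, exhaustive fill-edge and topology-search deciders |
| `triphy.generators` | random tree-derived matrices, the quadratic-edge interval family, certified-incompatible perturbations |
| `triphy.cli` | `triphy` command-line tool |

## Command line

```sh
triphy decide matrix.csv                 # JSON verdict; exit 0 compatible / 3 incompatible
triphy construct matrix.csv -o tree.nwk --labels nodes.tsv
triphy verify matrix.csv tree.nwk nodes.tsv
triphy separators matrix.csv [--json]    # legal minimal separators + crossing matrix
triphy generate random --n 8 --m 12 --seed 1 -o m.csv --tree-out truth.nwk
triphy generate mstar --n 7
triphy generate incompatible --n 5 --mode long_cycle
triphy debug oracle matrix.csv           # exhaustive reference decision (small inputs)
```

Matrix format: first row = character names, first column = taxon names,
cells = state symbols (at most three distinct per column; missing values
are rejected).  A digit-matrix dialect is available via
`--format phylip_digits` (`n m` header, then `name 0120...` lines).
Exit codes: 0 ok, 1 usage, 2 bad input, 3 incompatible data, 4 internal
inconsistency.

Construction output is plain Newick with nodes named `N0..Nk` plus a
sidecar TSV mapping each node to its species string (`*` = unassigned
state), its taxa, and any artificial edges used to join components of a
disconnected input.

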