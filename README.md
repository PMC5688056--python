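# csccp

Probability-ranked structure assignment for natural-product mixtures from
LC–MS neutral masses.

## The problem

Dereplicating a crude herbal extract means deciding, for each neutral
molecular weight pulled out of an LC–MS peak table, which known-scaffold /
side-chain combination most plausibly produced it. Given a seed scaffold
with *n* substituted positions, where position *i* offers *K<sub>i</sub>*
candidate side chains — each with a molecular weight *m<sub>i,x</sub>* (Da)
and an occurrence probability *p<sub>i,x</sub>* estimated from how often
that chain decorates that scaffold position in nature — and a target
neutral mass *W₀*, the task is

&nbsp;&nbsp;&nbsp;&nbsp;maximize&nbsp; ∏<sub>i=1..n</sub> p<sub>i,x<sub>i</sub></sub>
&nbsp;&nbsp;subject to&nbsp; Σ<sub>i=1..n</sub> m<sub>i,x<sub>i</sub></sub> = W₀,
&nbsp;&nbsp;x<sub>i</sub> ∈ {1..K<sub>i</sub>},

reporting the top *R* feasible assignments ranked by probability product.
This is a knapsack-style subset-selection problem (NP-complete in general),
but its mass structure makes dynamic programming effective in practice.

## Solvers

* **`brute_force_topR`** — exhaustive enumeration of all ∏K<sub>i</sub>
  assignments; the oracle for testing, guarded against large spaces.
* **`dp_solve`** — pseudo-polynomial dynamic program. Masses are scaled by
  10<sup>D</sup> and rounded to integers; a sparse cost table
  `C[s, w] → top-R products` with backpointers is filled over prefix
  lengths *s* = 1..*n* and reachable integer masses *w*, and the ranked
  assignments at `(n, W₀·10^D)` are reconstructed by backtracking. Exact
  when inputs carry ≤ D decimals, but cost grows with 10<sup>D</sup>·W₀.
* **`idp_solve`** — iterative variant that needs no precision parameter.
  Masses are truncated to whole Daltons, the final layer is queried over a
  small integer-mass window around the truncated target, candidates are
  filtered by their *exact* floating-point mass, and the per-cell rank
  budget R′ (starting at 10R) escalates tenfold only while the previous
  pass was provably incomplete. On realistic libraries one pass suffices,
  giving polynomial average-case behavior.

All solvers share one deterministic ranking (product descending,
lexicographically smallest assignment on ties), so their outputs are
comparable entry by entry.

On top of the solvers, `csccp.pipeline` expands a whole library — every
(scaffold, position set, target MW) triple becomes one job — and merges
results into probability-ranked candidate pools per scaffold and per
target mass, with optional template-based structure assembly and
reference-structure rank lookup.

## Worked example

A scaffold with three substituted positions, two candidate chains each:

| position | chain | mass (Da) | prob |
|---|---|---|---|
| 1 | p1c1 / p1c2 | 15 / 17 | 0.2 / 0.8 |
| 2 | p2c1 / p2c2 | 17 / 62 | 0.8 / 0.2 |
| 3 | p3c1 / p3c2 | 17 / 62 | 0.2 / 0.8 |

Exactly two of the eight assignments sum to 96 Da:

```sh
$ csccp solve --library src/csccp/data/example_library.tsv --mw 96 --algorithm idp --top 2
rank    product              total_sidechain_mw  assignment
1       0.5120000000000001   96.0                1=p1c2|2=p2c1|3=p3c2
2       0.03200000000000001  96.0                1=p1c2|2=p2c2|3=p3c1
```

Rank 1 picks the 17 Da chain at every position weighted 0.8·0.8·0.8 =
0.512; rank 2 swaps positions 2 and 3 into their improbable chains
(0.8·0.2·0.2 = 0.032). The same two solutions come back from `--algorithm
bf` and `--algorithm dp`, and the iterative solver finishes in a single
pass (logged to stderr).

The full pipeline runs the same way from a target-MW list:

```sh
csccp elucidate --library lib.tsv --mw-list mws.txt --top 10 --out-prefix report
```

writing `report.tsv` / `report.json` with ranked candidates pooled per
scaffold and per target mass.

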