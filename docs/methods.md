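# Methods

## Model

An instance is an ordered list of substituted positions on a seed scaffold.
Position *i* carries K<sub>i</sub> candidate side chains; chain *x* has a
molecular weight m<sub>i,x</sub> > 0 (Da, floating point, up to six printed
decimals) and an occurrence probability p<sub>i,x</sub> ∈ (0, 1] — the
relative frequency with which that chain decorates that scaffold position
across known natural products. A solution assigns exactly one chain per
position; it is *feasible* when the chain masses sum to the target neutral
mass W₀ (an LC–MS-derived value), and solutions are ranked by the product
of their probabilities. The requested output is the top R feasible
assignments.

Assumptions worth stating explicitly:

* Positions are independent: the probability of a full decoration is the
  product of per-position probabilities. Real co-occurrence correlations
  between side chains are not modeled.
* Probabilities may arrive as raw counts (normalized per position at load
  time, zero-count chains dropped) or as precomputed probabilities.
  Per-position probabilities that do not sum to one are accepted with a
  warning rather than rejected, since some curation pipelines normalize
  across a whole scaffold instead.
* Mass equality is a tolerance test on floating-point Daltons:
  |Σm − W₀| ≤ `mass_tol`, default 5·10⁻⁷ Da (half of the sixth printed
  decimal). Adduct/charge deconvolution to neutral mass happens upstream.

## Cost-table dynamic program

Define C(s, w, r) as the r-th largest probability product over assignments
of the first *s* positions whose (integerized) masses sum to *w*. The
recurrence extends prefixes one position at a time:

    C(s, w, 1:R) = top-R over x ∈ 1..K_s, r ∈ 1..R of
                   p_{s,x} · C(s−1, w − m'_{s,x}, r)

seeded by C(0, 0, 1) = 1 and C(0, w, r) = 0 elsewhere. The result order is
invariant to the order in which positions are processed. The table is
stored sparsely — only reachable (s, w) states exist — because a dense
array over w ≤ W₀·10⁶ would be hundreds of millions of cells while the
number of reachable states is bounded by the number of distinct prefix
mass sums. Each cell keeps its ranked values together with backpointers
(chosen chain, predecessor rank); ranked assignments are reconstructed by
walking backpointers to the origin.

For the scaled solver (`dp_solve`) masses are integerized as
⌊m·10<sup>D</sup> + 0.5⌋ (round half up), D defaulting to 6, which is
exact when inputs carry at most D decimals. The per-cell merge is a
partial sort of at most K<sub>s</sub>·R candidates. Because the table size
scales with 10<sup>D</sup>·W₀, there is a precision break-even point
log₁₀(∏K<sub>i</sub>)/W₀ beyond which plain enumeration is cheaper;
`dp_decimals_threshold` computes it and `dp_solve` logs an advisory (at
INFO level — for small demonstration instances it is almost always the
case, and enumeration is then also fast) when the configured D exceeds it.

## Iterative solver

`idp_solve` removes the precision parameter altogether. Masses and target
are truncated to whole Daltons (⌊m + 0.5⌋ — the formula-level definition;
e.g. a target of 400.03 becomes 400). Truncation moves each of the *n*
masses by at most 0.5 Da, so every exact match lands, in truncated
coordinates, within a window of ±⌈(n+1)/2⌉ integer Daltons around the
truncated target; the solver collects all final-layer cells in that
window. The window is the symmetric integer superset of the exact
(asymmetric, real-valued) bound — a superset can only admit extra decoys,
which the subsequent exact-mass filter removes.

Because many distinct exact masses collapse into one truncated cell, the
per-cell rank budget is enlarged to R′ = 10R so true matches are unlikely
to be pushed below the cut by coincident-mass decoys. Each pass:

1. run the truncated DP with budget R′, pruning states beyond the window's
   upper edge;
2. collect window candidates and keep those whose exact floating-point
   mass matches W₀ within `mass_tol`;
3. stop if ≥ R matches are in hand; otherwise stop if the pass was
   *exhaustive* — no cell anywhere overflowed its rank budget, so no
   larger R′ can surface anything new; otherwise multiply R′ by ten and
   repeat, giving up once R′ exceeds ∏K<sub>i</sub> (strictly greater, at
   which point a pass is exhaustive by construction anyway).

The exhaustiveness test is tracked as a single overflow flag during table
construction. It is deliberately stronger than the simpler "fewer than R
solutions found in the first pass" early stop: that phrasing is a special
case (fewer than R window candidates implies no overflow at R′ ≥ 10R), but
taken literally on the filtered solution set it would terminate even when
a saturated cell is hiding true matches below the cut — precisely the
situation the precision-adversarial generator constructs, where more than
10R decoys outrank every true match and a second pass is required for
correctness. With the overflow flag the solver is exact whenever it stops,
at the price of an occasional extra pass.

The loop count L is the performance driver: one pass costs
O(nW″R′K̄ log R′K̄) on truncated masses (W″ no longer carries the 10^D
factor). On masses with ≤ 2 decimals and realistic library sizes the first
pass is almost always decisive; the test suite checks a ≥ 95 % one-pass
rate over 200 seeded planted instances, and the adversarial generator
(below) exercises the ≥ 2-pass path.

## Determinism and tie-breaking

All solvers rank by product descending and break exact ties by the
lexicographically smallest assignment vector. Internally each cost-table
entry carries its prefix assignment so ties are broken identically during
table construction and final sorting; products are accumulated
left-to-right in slot order in every solver, making ranked outputs
bit-identical across bf/dp/idp and across runs. Permuting slot order
changes association order of the float product (last-ulp effects), so the
permutation-invariance tests compare products at 10⁻¹² relative tolerance
while assignments (as position→chain mappings) must match exactly.

## Synthetic generators

The generators in `csccp.fixtures` are pure functions of a seed (numpy
PCG64) and emulate small side-chain libraries: 2–6 substituted positions,
2–5 chains per position, masses uniform in 10–70 Da rounded to 0–6
decimals (the 10–70 Da range brackets common O-/N-/C-substituents:
methyl ≈ 15, hydroxyl ≈ 17, acetyl ≈ 43, glycosyl-scale fragments toward
the top), Dirichlet(1) probabilities per position.

* `planted_instance` sets W₀ to the exact mass sum of a random assignment,
  then makes further assignments feasible by switching a single position
  of a planted assignment to a chain unused by any planted assignment and
  rewriting that chain's mass to close the gap exactly at the configured
  decimal precision. The rewritten (position, chain) pair is never used by
  existing planted assignments, so their feasibility is preserved; the
  procedure guarantees the planted set is a subset of the true match set
  without biasing probabilities.
* `precision_adversarial_instance` builds the case truncation handles
  worst: within each of three positions all chains share one integer mass
  and differ only at the sixth decimal, so all 27 assignments collapse
  into a single truncated cell; the target is the exact mass of the least
  probable assignment, and every decoy outranks it. The first iterative
  pass cannot see the match and the solver must escalate.

What the generators do *not* emulate: real occurrence-frequency skew
(database-derived probabilities are heavily long-tailed), chemically
correlated side chains, isobaric chains at equal printed precision, or
library sizes in the tens of chains per position. Passing tests therefore
demonstrate algorithmic correctness and the claimed iteration behavior on
libraries of realistic *shape*, not predictive accuracy on any particular
compound database.

## Pipeline conventions

One elucidation run expands to N<sub>p</sub> × Σ N<sub>k</sub> jobs
(targets × position sets summed over scaffolds). Ranked pools are built
per (scaffold, target MW), merging all position sets of that scaffold;
candidates that assemble identically from different position sets are
distinct hypotheses and are kept separate unless `--dedupe` is passed
(which keeps the best rank). A second, cross-scaffold pooling per target
MW is always emitted alongside, since validation workflows sometimes quote
one rank per observed mass; both are in the JSON report, the TSV carries
the per-scaffold pools. Reference matching is string equality on the
canonical assembled form (`scaffold|pos=chain|...`, or the template
substitution when a template is provided), reporting the best per-pool
rank.

## Worked example and its target mass

The packaged example library (three positions, two chains each, masses
[[15,17],[17,62],[17,62]], probabilities [[0.2,0.8],[0.8,0.2],[0.2,0.8]])
is solved at W₀ = 96 Da. Enumeration of the eight assignments yields two
total-mass classes of size two — 94 Da (products 0.128/0.008) and 96 Da
(products 0.512/0.032); the intended demonstration class is the one whose
ranked products are highest, 96 Da, and the acceptance script selects it by
that rule rather than hard-coding the mass. (Accounts of this example
sometimes quote a target of 98 Da, which no pair of the printed masses
realizes; the products 0.512/0.032 pin the class unambiguously.)

## Numerical and scale choices

* Default R = 10: validated natural-product assignments in published case
  studies overwhelmingly rank within the top ten.
* Default D = 6, matching the precision of high-resolution neutral masses;
  `--decimals auto` infers D as the maximum decimals printed in the
  library file, which keeps the scaled DP exact and as small as possible.
* `mass_tol` = 5·10⁻⁷ Da: half of the sixth printed decimal. Set it to 0
  for strict float equality, or larger to absorb upstream mass error.
* Brute force refuses spaces above 10⁷ assignments (configurable guard).
* Test corpora use 200 seeded planted instances (n ≤ 6, K ≤ 5) for the
  oracle-equivalence and iteration-behavior suites and 20–100 seeds for
  structural invariants — sizes at which the exhaustive oracle stays
  instantaneous while covering the solver's branching behavior.

## Known limitations

* Probability products underflow double precision only near n ≈ 300
  positions at p ≈ 10⁻¹ each; real scaffolds have n ≤ ~15, so products are
  computed in plain double precision.
* The iterative solver's ≥-R stopping rule trusts that R matches found in
  a pass are the true top R; a saturated cell could in principle hide a
  better match below an overflowing cut. The escalated budget R′ ≥ 10R
  makes this require more than 10R same-cell decoys between two true
  matches — not observed outside deliberately adversarial constructions,
  and those are covered by the exhaustiveness rule.
* Structure assembly is textual placeholder substitution; no valence or
  chemical-validity checking is performed.
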