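"""Top-R solvers for the side-chain mass-matching problem.

Three routes to the same answer, with very different costs:

``brute_force_topR``
    Enumerates all ``prod K_i`` assignments.  Exact, exponential; used as
    the oracle in tests and refuses spaces above a configurable guard.

``dp_solve``
    Pseudo-polynomial dynamic program over masses scaled to integers by
    ``10**D``.  A sparse cost table maps ``(prefix length s, integer
    weight w)`` to the top-``R`` probability products reachable with that
    prefix mass, each with a backpointer for reconstruction.  Runtime grows
    with ``10**D * W0``, so high mass precision is expensive — see
    :func:`dp_decimals_threshold`.

``idp_solve``
    Iterative variant on masses truncated to whole Daltons.  Truncation
    collapses many distinct exact masses into one integer cell, so the
    solver (1) widens the final-layer query to a small window of integer
    weights around the truncated target, (2) keeps an enlarged rank budget
    ``R'`` per cell, (3) filters candidates by their *exact* floating-point
    mass against the original target, and (4) escalates ``R'`` tenfold and
    repeats only when the previous pass was provably incomplete.  On typical
    libraries one pass suffices and the runtime is polynomial on average.

All three rank by probability product, breaking ties by the
lexicographically smallest assignment vector, so their outputs are directly
comparable entry by entry.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    CsccpInstance,
    SolutionEntry,
    TopRList,
    candidate_space_size,
    integerize,
    make_solution_entry,
)

__all__ = [
    "CostCell",
    "CostTable",
    "SolverResult",
    "brute_force_topR",
    "merge_topR",
    "dp_solve",
    "idp_solve",
    "backtrack",
    "weight_window",
    "real_weight_matches",
    "dp_decimals_threshold",
    "DEFAULT_MASS_TOL",
    "BRUTE_FORCE_GUARD",
]

logger = logging.getLogger(__name__)

#: Exact-mass tolerance in Da used when comparing a candidate's
#: floating-point mass sum with the target MW.  Half of the last (sixth)
#: decimal place an LC-MS-derived neutral mass is reported with.
DEFAULT_MASS_TOL = 0.5e-6

#: Refuse brute-force enumeration above this many combinations.
BRUTE_FORCE_GUARD = 10**7


@dataclass(frozen=True)
class _CellEntry:
    """One ranked value inside a cost cell.

    ``value`` is the probability product of the prefix, ``prefix`` the
    1-based choices made so far (carried for deterministic tie-breaking),
    ``back`` the backpointer ``(x_s, predecessor rank)`` or ``None`` at the
    empty prefix.
    """

    value: float
    prefix: tuple[int, ...]
    back: tuple[int, int] | None


#: Ordered top-R values with backpointers for one (s, w) state.
CostCell = list[_CellEntry]


def _cell_key(entry: _CellEntry) -> tuple[float, tuple[int, ...]]:
    return (-entry.value, entry.prefix)


@dataclass
class CostTable:
    """Sparse map ``(s, w) -> CostCell`` plus the integer weights needed to
    walk backpointers.  Cell ``(0, 0)`` holds the single seed value 1."""

    int_weights: tuple[tuple[int, ...], ...]
    layers: list[dict[int, CostCell]] = field(default_factory=list)
    truncated: bool = False  # True when some cell overflowed its rank budget

    def cell(self, s: int, w: int) -> CostCell | None:
        if not (0 <= s < len(self.layers)):
            return None
        return self.layers[s].get(w)

    def layer(self, s: int) -> dict[int, CostCell]:
        return self.layers[s]


def _build_table(
    instance: CsccpInstance,
    int_weights: tuple[tuple[int, ...], ...],
    rank_budget: int,
    max_weight: int,
) -> CostTable:
    """Forward DP over prefix length s = 0..n and integer weight <= max_weight.

    Seeds the table with the single empty-prefix state (weight 0, value 1)
    and pushes each kept state forward through every side-chain choice,
    keeping the ``rank_budget`` best values per cell.  States whose weight
    would exceed ``max_weight`` are never created, which is also the
    boundary skip for side chains heavier than the remaining budget.
    """
    table = CostTable(int_weights=int_weights)
    table.layers.append({0: [_CellEntry(1.0, (), None)]})
    for s, slot in enumerate(instance.slots, start=1):
        weights = int_weights[s - 1]
        probs = tuple(o.prob for o in slot.options)
        candidates: dict[int, CostCell] = {}
        for w_prev, cell in table.layers[s - 1].items():
            for parent_rank, entry in enumerate(cell, start=1):
                for x in range(1, len(slot) + 1):
                    w_new = w_prev + weights[x - 1]
                    if w_new > max_weight:
                        continue
                    candidates.setdefault(w_new, []).append(
                        _CellEntry(
                            value=entry.value * probs[x - 1],
                            prefix=entry.prefix + (x,),
                            back=(x, parent_rank),
                        )
                    )
        layer: dict[int, CostCell] = {}
        for w in sorted(candidates):
            lst = candidates[w]
            if len(lst) > rank_budget:
                table.truncated = True
            lst.sort(key=_cell_key)
            layer[w] = lst[:rank_budget]
        table.layers.append(layer)
    return table


@dataclass
class SolverResult:
    """Ranked solutions plus run metadata.

    ``loop_count``/``final_Rprime`` are set by the iterative solver only;
    ``d_used`` by the scaled DP only.
    """

    top: TopRList
    algorithm: str
    loop_count: int | None = None
    final_Rprime: int | None = None
    d_used: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("bf", "dp", "idp"):
            raise ValueError(f"unknown algorithm tag {self.algorithm!r}")
        if self.algorithm == "idp" and (self.loop_count is None or self.loop_count < 1):
            raise ValueError("idp results must carry a loop_count >= 1")

    def ranked(self) -> list[tuple[tuple[int, ...], float]]:
        """(assignment, product) pairs in rank order — handy for comparison."""
        return [(e.assignment, e.product) for e in self.top]


def _entry_sort_key(e: SolutionEntry) -> tuple[float, tuple[int, ...]]:
    return (-e.product, e.assignment)


def brute_force_topR(
    instance: CsccpInstance,
    tol: float = DEFAULT_MASS_TOL,
    R: int | None = None,
    guard: int = BRUTE_FORCE_GUARD,
) -> SolverResult:
    """Enumerate every assignment and keep the top R whose exact mass is
    within ``tol`` Da of the target.  Refuses spaces larger than ``guard``."""
    space = candidate_space_size(instance)
    if space > guard:
        raise ValueError(
            f"brute force refused: candidate space {space} exceeds guard {guard}"
        )
    R = instance.R if R is None else R
    target = instance.target_mw
    slot_probs = [tuple(o.prob for o in slot.options) for slot in instance.slots]
    slot_mws = [tuple(o.mw for o in slot.options) for slot in instance.slots]
    matches: list[SolutionEntry] = []
    for combo in itertools.product(*(range(1, len(s) + 1) for s in instance.slots)):
        product = 1.0
        mass = 0.0
        for i, x in enumerate(combo):
            product *= slot_probs[i][x - 1]
            mass += slot_mws[i][x - 1]
        if abs(mass - target) <= tol:
            matches.append(SolutionEntry(assignment=combo, product=product, exact_mass=mass))
    matches.sort(key=_entry_sort_key)
    return SolverResult(top=TopRList(matches[:R]), algorithm="bf")


def merge_topR(candidates: Iterable[tuple[float, object]], R: int) -> list[tuple[float, object]]:
    """Keep the R largest products, non-increasing; ties keep every distinct
    provenance entry, in input order (stable partial sort)."""
    if R < 0:
        raise ValueError(f"R must be >= 0, got {R}")
    return sorted(candidates, key=lambda c: -c[0])[:R]


def dp_decimals_threshold(instance: CsccpInstance) -> float:
    """Mass-precision break-even point ``log10(prod K_i) / W0``.

    Above this many decimal places the scaled DP's table outgrows the raw
    enumeration, so brute force becomes the cheaper route.  Purely advisory.
    """
    return math.log10(candidate_space_size(instance)) / instance.target_mw


def dp_solve(
    instance: CsccpInstance,
    D: int | None = None,
    R: int | None = None,
) -> SolverResult:
    """Exact top-R via the scaled dynamic program.

    Masses are scaled by ``10**D`` and rounded to integers, the sparse cost
    table is filled for prefix lengths 1..n, and the top-R list at
    ``(n, W0')`` is backtracked into full assignments.  Exact whenever the
    input masses carry at most ``D`` decimal places.
    """
    D = instance.D if D is None else D
    R = instance.R if R is None else R
    threshold = dp_decimals_threshold(instance)
    if D > threshold:
        logger.info(
            "D=%d exceeds the break-even precision %.4g for this instance; "
            "the scaled DP may cost more than brute force",
            D,
            threshold,
        )
    int_inst = integerize(instance, "scaled", D)
    table = _build_table(instance, int_inst.int_weights, rank_budget=R, max_weight=int_inst.int_target)
    cell = table.cell(instance.n, int_inst.int_target) or []
    entries = []
    for rank in range(1, len(cell) + 1):
        assignment = backtrack(table, instance.n, int_inst.int_target, rank)
        entries.append(make_solution_entry(instance, assignment))
    return SolverResult(top=TopRList(entries), algorithm="dp", d_used=D)


def backtrack(table: CostTable, s: int, w: int, rank: int) -> tuple[int, ...]:
    """Follow backpointers from cell ``(s, w)`` at ``rank`` down to the empty
    prefix, returning the 1-based assignment ``(x_1, .., x_s)``."""
    cell = table.cell(s, w)
    if cell is None or rank < 1 or rank > len(cell):
        raise KeyError(f"no rank {rank} entry at cell ({s}, {w})")
    choices: list[int] = []
    cur_s, cur_w, cur_rank = s, w, rank
    while cur_s > 0:
        entry = table.cell(cur_s, cur_w)[cur_rank - 1]
        x, parent_rank = entry.back
        choices.append(x)
        cur_w -= table.int_weights[cur_s - 1][x - 1]
        cur_s -= 1
        cur_rank = parent_rank
    return tuple(reversed(choices))


def weight_window(n: int, int_target: int) -> tuple[int, int]:
    """Integer weight window around the truncated target that is guaranteed
    to contain every assignment whose exact mass equals the target.

    Each of the ``n`` masses moves by at most 0.5 Da under half-up rounding,
    so the truncated total of an exact match lies within ``ceil((n+1)/2)``
    of the truncated target; the window is the symmetric integer superset
    of that range, clipped at zero.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    half = math.ceil((n + 1) / 2)
    return (max(0, int_target - half), int_target + half)


def real_weight_matches(entry: SolutionEntry, target_mw: float, tol: float = DEFAULT_MASS_TOL) -> bool:
    """True iff the entry's exact floating-point mass is within ``tol`` Da
    of the original (un-truncated) target."""
    return abs(entry.exact_mass - target_mw) <= tol


def idp_solve(
    instance: CsccpInstance,
    R: int | None = None,
    tol: float = DEFAULT_MASS_TOL,
) -> SolverResult:
    """Iterative top-R on whole-Dalton masses with exact-mass filtering.

    Each pass runs the dynamic program on truncated integer masses with an
    enlarged per-cell rank budget ``R'`` (10R, then 100R, ...), collects
    every candidate in the final-layer weight window, and keeps those whose
    exact floating-point mass matches the target.  The loop stops when

    * at least ``R`` exact matches are in hand, or
    * the pass was exhaustive — no cell anywhere overflowed its rank
      budget, so a larger ``R'`` cannot surface new candidates, or
    * ``R'`` already exceeds the whole candidate space.
    """
    R = instance.R if R is None else R
    int_inst = integerize(instance, "truncated")
    lo, hi = weight_window(instance.n, int_inst.int_target)
    space = candidate_space_size(instance)
    r_prime = 10 * R
    loops = 0
    matches: list[SolutionEntry] = []
    while True:
        loops += 1
        table = _build_table(
            instance, int_inst.int_weights, rank_budget=r_prime, max_weight=hi
        )
        matches = []
        final_layer = table.layer(instance.n)
        for w in range(lo, hi + 1):
            for centry in final_layer.get(w, ()):  # window collection
                entry = make_solution_entry(instance, centry.prefix)
                if real_weight_matches(entry, instance.target_mw, tol):
                    matches.append(entry)
        matches.sort(key=_entry_sort_key)
        if len(matches) >= R:
            break
        if not table.truncated:
            break  # pass was exhaustive; escalation cannot add solutions
        if r_prime > space:
            break
        r_prime *= 10
    return SolverResult(
        top=TopRList(matches[:R]),
        algorithm="idp",
        loop_count=loops,
        final_Rprime=r_prime,
    )
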