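"""Domain types for scaffold/side-chain mass matching.

The core object is a :class:`CsccpInstance`: an ordered set of substituted
positions on a chemical scaffold, each carrying a list of candidate side
chains with a molecular weight (Da) and an occurrence probability, plus a
target neutral molecular weight ``W0`` taken from an LC-MS peak table.  A
solution assigns one side chain per position so that the side-chain masses
sum to ``W0``; solutions are ranked by the product of their occurrence
probabilities and the ``R`` best are reported.

Masses are floating-point Da throughout the model layer; the solvers work on
integerized copies produced by :func:`integerize` (either scaled by
``10**D`` to preserve ``D`` decimal places, or truncated to whole Daltons
for the iterative solver).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "SideChainOption",
    "PositionSlot",
    "CsccpInstance",
    "IntegerizedInstance",
    "SolutionEntry",
    "TopRList",
    "Scaffold",
    "PositionSetCatalog",
    "normalize_counts_to_probs",
    "integerize",
    "candidate_space_size",
]


@dataclass(frozen=True)
class SideChainOption:
    """One candidate substituent: a label, an optional SMILES fragment,
    a molecular weight in Da and an occurrence probability in (0, 1]."""

    id: str
    mw: float
    prob: float
    smiles: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("side-chain id must be non-empty")
        if not (self.mw > 0):
            raise ValueError(f"side chain {self.id!r}: mw must be > 0, got {self.mw}")
        if not (0 < self.prob <= 1):
            raise ValueError(
                f"side chain {self.id!r}: prob must be in (0, 1], got {self.prob}"
            )


@dataclass(frozen=True)
class PositionSlot:
    """A substituted position (1-based ``index``) and its candidate side
    chains.  Option order is the file order and fixes downstream
    tie-breaking."""

    index: int
    options: tuple[SideChainOption, ...]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"position index must be >= 1, got {self.index}")
        if len(self.options) < 1:
            raise ValueError(f"position {self.index}: needs at least one side chain")
        ids = [o.id for o in self.options]
        if len(set(ids)) != len(ids):
            raise ValueError(f"position {self.index}: duplicate side-chain ids")
        object.__setattr__(self, "options", tuple(self.options))

    def __len__(self) -> int:
        return len(self.options)


@dataclass(frozen=True)
class CsccpInstance:
    """One solvable problem: ordered position slots, a target MW ``W0`` (Da),
    the requested solution count ``R`` and the mass decimal precision ``D``."""

    slots: tuple[PositionSlot, ...]
    target_mw: float
    R: int = 10
    D: int = 6

    def __post_init__(self) -> None:
        if len(self.slots) < 1:
            raise ValueError("instance needs at least one position slot")
        if not (self.target_mw > 0):
            raise ValueError(f"target_mw must be > 0, got {self.target_mw}")
        if self.R < 1:
            raise ValueError(f"R must be >= 1, got {self.R}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        object.__setattr__(self, "slots", tuple(self.slots))

    @property
    def n(self) -> int:
        return len(self.slots)

    def permuted(self, order: Sequence[int]) -> "CsccpInstance":
        """Return a copy with slots reordered by ``order`` (0-based into the
        current slot tuple).  Solution sets are invariant under this."""
        if sorted(order) != list(range(self.n)):
            raise ValueError("order must be a permutation of the slot indices")
        return CsccpInstance(
            slots=tuple(self.slots[i] for i in order),
            target_mw=self.target_mw,
            R=self.R,
            D=self.D,
        )


@dataclass(frozen=True)
class IntegerizedInstance:
    """Integer copy of an instance's masses.

    ``mode='scaled'`` multiplies by ``10**D`` before rounding half-up, so
    ``D`` decimal places survive; ``mode='truncated'`` rounds each mass to
    whole Daltons (``floor(m + 0.5)``), the representation the iterative
    solver works on.
    """

    int_weights: tuple[tuple[int, ...], ...]
    int_target: int
    mode: str
    lam: int

    def __post_init__(self) -> None:
        if self.mode not in ("scaled", "truncated"):
            raise ValueError(f"mode must be 'scaled' or 'truncated', got {self.mode!r}")
        for row in self.int_weights:
            for w in row:
                if w < 0:
                    raise ValueError("integerized weights must be non-negative")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def integerize(instance: CsccpInstance, mode: str, D: int | None = None) -> IntegerizedInstance:
    """Map an instance's floating-point masses to integers.

    ``scaled`` applies ``floor(m * 10**D + 0.5)`` (default ``D`` from the
    instance); ``truncated`` applies ``floor(m + 0.5)`` and ignores ``D``.
    """
    if mode == "scaled":
        d = instance.D if D is None else D
        lam = 10**d
        weights = tuple(
            tuple(_round_half_up(o.mw * lam) for o in slot.options)
            for slot in instance.slots
        )
        target = _round_half_up(instance.target_mw * lam)
    elif mode == "truncated":
        lam = 1
        weights = tuple(
            tuple(_round_half_up(o.mw) for o in slot.options) for slot in instance.slots
        )
        target = _round_half_up(instance.target_mw)
    else:
        raise ValueError(f"unknown integerization mode {mode!r}")
    return IntegerizedInstance(int_weights=weights, int_target=target, mode=mode, lam=lam)


def candidate_space_size(instance: CsccpInstance) -> int:
    """Number of full assignments, ``prod_i K_i``."""
    return math.prod(len(slot) for slot in instance.slots)


def normalize_counts_to_probs(counts: Mapping[str, float]) -> dict[str, float]:
    """Turn raw occurrence counts for one position into probabilities.

    Zero-count options are dropped (they can never appear in an optimum and
    keeping them would allow zero products).  Raises ``ValueError`` when no
    option has a positive count.
    """
    total = 0.0
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for option {name!r}: {c}")
        total += c
    if total <= 0:
        raise ValueError("all counts are zero; position has no usable side chain")
    return {name: c / total for name, c in counts.items() if c > 0}


def make_solution_entry(instance: CsccpInstance, assignment: Sequence[int]) -> "SolutionEntry":
    """Build a :class:`SolutionEntry` for a full assignment.

    Product and mass are accumulated left-to-right over the instance's slot
    order so that every solver produces bit-identical floats for the same
    assignment of the same instance.
    """
    if len(assignment) != instance.n:
        raise ValueError(
            f"assignment length {len(assignment)} != number of slots {instance.n}"
        )
    product = 1.0
    mass = 0.0
    for slot, x in zip(instance.slots, assignment):
        if not (1 <= x <= len(slot)):
            raise ValueError(f"position {slot.index}: choice {x} out of range 1..{len(slot)}")
        opt = slot.options[x - 1]
        product *= opt.prob
        mass += opt.mw
    return SolutionEntry(assignment=tuple(assignment), product=product, exact_mass=mass)


@dataclass(frozen=True)
class SolutionEntry:
    """A full assignment: 1-based side-chain choices per slot, the product of
    the chosen probabilities and the exact floating-point mass sum (Da)."""

    assignment: tuple[int, ...]
    product: float
    exact_mass: float

    def ids(self, instance: CsccpInstance) -> tuple[str, ...]:
        """Chosen side-chain ids in slot order."""
        return tuple(
            slot.options[x - 1].id for slot, x in zip(instance.slots, self.assignment)
        )

    def mapping(self, instance: CsccpInstance) -> dict[int, str]:
        """Position index -> chosen side-chain id (slot-order independent)."""
        return {
            slot.index: slot.options[x - 1].id
            for slot, x in zip(instance.slots, self.assignment)
        }


@dataclass
class TopRList:
    """Ranked solutions, non-increasing in product, at most ``R`` entries.
    Equal products are ordered by the lexicographically smallest assignment."""

    entries: list[SolutionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.entries, self.entries[1:]):
            if a.product < b.product:
                raise ValueError("TopRList entries must be non-increasing in product")
        seen = set()
        for e in self.entries:
            if e.assignment in seen:
                raise ValueError(f"duplicate assignment {e.assignment} in TopRList")
            seen.add(e.assignment)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SolutionEntry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> SolutionEntry:
        return self.entries[i]

    def products(self) -> list[float]:
        return [e.product for e in self.entries]

    def assignments(self) -> list[tuple[int, ...]]:
        return [e.assignment for e in self.entries]


@dataclass(frozen=True)
class Scaffold:
    """A seed scaffold: core substructure shared by a compound family, with
    one or more named position sets (choices of which positions carry
    substituents).  ``template`` may hold a structure string with ``R1..Rn``
    placeholders for assembly."""

    scaffold_id: str
    position_sets: dict[str, tuple[PositionSlot, ...]]
    template: str = ""

    def __post_init__(self) -> None:
        if not self.scaffold_id:
            raise ValueError("scaffold_id must be non-empty")
        if not self.position_sets:
            raise ValueError(f"scaffold {self.scaffold_id!r}: needs >= 1 position set")
        for name, slots in self.position_sets.items():
            idx = [s.index for s in slots]
            if len(set(idx)) != len(idx):
                raise ValueError(
                    f"scaffold {self.scaffold_id!r} set {name!r}: duplicate position indices"
                )

    @property
    def n_position_sets(self) -> int:
        return len(self.position_sets)


@dataclass
class PositionSetCatalog:
    """Ordered collection of scaffolds loaded from a side-chain library.

    ``mass_decimals`` records the largest number of decimal places seen in
    the source masses; readers fill it in so callers can pick the scaled
    DP's ``D`` automatically.
    """

    scaffolds: dict[str, Scaffold] = field(default_factory=dict)
    mass_decimals: int = 6

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self.scaffolds.values())

    def add(self, scaffold: Scaffold) -> None:
        if scaffold.scaffold_id in self.scaffolds:
            raise ValueError(f"duplicate scaffold id {scaffold.scaffold_id!r}")
        self.scaffolds[scaffold.scaffold_id] = scaffold

    def get(self, scaffold_id: str) -> Scaffold:
        try:
            return self.scaffolds[scaffold_id]
        except KeyError:
            raise KeyError(f"unknown scaffold {scaffold_id!r}") from None
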