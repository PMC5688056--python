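"""Seeded synthetic instance generators.

Every generator is a pure function of a :class:`GeneratorSpec` (or a bare
seed): randomness comes from one numpy ``default_rng`` (PCG64) seeded from
the spec, so the same spec always yields byte-identical instances.  They
exist so that every solver property — oracle equivalence, early stopping,
precision escalation — can be exercised without any external data.

Defaults mirror small natural-product side-chain libraries: a handful of
substituted positions, a few candidate chains per position, masses of tens
of Daltons printed with at most six decimals, and occurrence probabilities
that sum to one per position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    CsccpInstance,
    PositionSetCatalog,
    PositionSlot,
    Scaffold,
    SideChainOption,
)

__all__ = [
    "GeneratorSpec",
    "random_instance",
    "planted_instance",
    "precision_adversarial_instance",
    "worked_example_instance",
    "synthetic_catalog",
    "catalog_from_instance",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible recipe for one random instance.

    ``K`` is either one side-chain count for every position or a per-position
    sequence; masses are drawn uniformly in ``weight_range`` (Da) and rounded
    to ``decimals`` places; probabilities are Dirichlet(``alpha``) per
    position, hence positive and normalized.
    """

    seed: int
    n: int = 3
    K: int | tuple[int, ...] = 3
    weight_range: tuple[float, float] = (10.0, 70.0)
    decimals: int = 2
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0 <= self.decimals <= 6):
            raise ValueError(f"decimals must be in 0..6, got {self.decimals}")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ValueError(f"weight range must be positive, got {self.weight_range}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")

    def k_per_position(self) -> tuple[int, ...]:
        if isinstance(self.K, int):
            return (self.K,) * self.n
        if len(self.K) != self.n:
            raise ValueError(f"K sequence length {len(self.K)} != n {self.n}")
        return tuple(self.K)


def _draw_slots(spec: GeneratorSpec, rng: np.random.Generator) -> list[PositionSlot]:
    lo, hi = spec.weight_range
    slots = []
    for i, k in enumerate(spec.k_per_position(), start=1):
        weights = np.round(rng.uniform(lo, hi, size=k), spec.decimals)
        probs = rng.dirichlet(np.full(k, spec.alpha))
        while probs.min() < 1e-9:  # keep probabilities strictly positive
            probs = rng.dirichlet(np.full(k, spec.alpha))
        options = tuple(
            SideChainOption(id=f"p{i}c{j + 1}", mw=float(weights[j]), prob=float(probs[j]))
            for j in range(k)
        )
        slots.append(PositionSlot(index=i, options=options))
    return slots


def random_instance(spec: GeneratorSpec, R: int = 10) -> CsccpInstance:
    """Random instance with an independently drawn target MW.

    The target is uniform over the attainable mass range and rounded to the
    spec's decimals, so it may well be infeasible — useful for exercising
    empty-result paths.
    """
    rng = np.random.default_rng(spec.seed)
    slots = _draw_slots(spec, rng)
    lo, hi = spec.weight_range
    target = float(np.round(rng.uniform(spec.n * lo, spec.n * hi), spec.decimals))
    return CsccpInstance(slots=tuple(slots), target_mw=target, R=R, D=spec.decimals)


def _exact_match_assignments(
    instance: CsccpInstance, tol: float = 0.5e-6
) -> list[tuple[int, ...]]:
    """All assignments whose mass sum hits the target within ``tol`` Da
    (plain enumeration; generator-internal, not a solver)."""
    out = []
    mws = [tuple(o.mw for o in slot.options) for slot in instance.slots]
    for combo in itertools.product(*(range(1, len(s) + 1) for s in instance.slots)):
        mass = 0.0
        for i, x in enumerate(combo):
            mass += mws[i][x - 1]
        if abs(mass - instance.target_mw) <= tol:
            out.append(combo)
    return out


def planted_instance(
    spec: GeneratorSpec, n_feasible: int = 1, R: int = 10, max_retries: int = 500
) -> tuple[CsccpInstance, list[tuple[int, ...]]]:
    """Instance whose target MW is the exact mass sum of a planted assignment.

    Additional assignments are made feasible by weight surgery: pick an
    assignment, pick a position where its side chain is untouched by every
    already-planted assignment, and rewrite that chain's mass so the total
    closes the gap exactly at the spec's decimal precision.  Loops until at
    least ``n_feasible`` assignments match, then returns the instance and
    the planted set.
    """
    if n_feasible < 1:
        raise ValueError(f"n_feasible must be >= 1, got {n_feasible}")
    rng = np.random.default_rng(spec.seed)
    slots = _draw_slots(spec, rng)
    k = spec.k_per_position()
    first = tuple(int(rng.integers(1, ki + 1)) for ki in k)
    target = round(sum(slots[i].options[x - 1].mw for i, x in enumerate(first)), spec.decimals)
    instance = CsccpInstance(slots=tuple(slots), target_mw=target, R=R, D=spec.decimals)
    planted = [first]

    retries = 0
    while len(_exact_match_assignments(instance)) < n_feasible:
        retries += 1
        if retries > max_retries:
            raise RuntimeError(
                f"weight surgery failed to plant {n_feasible} feasible assignments "
                f"after {max_retries} attempts (seed {spec.seed})"
            )
        # Derive a fresh feasible assignment from a planted one: switch a
        # single position to an option no planted assignment uses, then
        # rewrite that option's mass to close the gap exactly.  Planted
        # assignments never touch the rewritten (position, option) pair, so
        # their sums are preserved.
        free_positions = [
            i
            for i in range(instance.n)
            if any(all(p[i] != o for p in planted) for o in range(1, k[i] + 1))
        ]
        if not free_positions:
            raise RuntimeError(
                f"cannot plant {n_feasible} feasible assignments: only "
                f"{1 + sum(ki - 1 for ki in k)} distinct single-switch "
                f"assignments exist (seed {spec.seed})"
            )
        pos = int(rng.choice(free_positions))
        unused = [o for o in range(1, k[pos] + 1) if all(p[pos] != o for p in planted)]
        option_idx = int(rng.choice(unused))
        base = planted[int(rng.integers(0, len(planted)))]
        combo = base[:pos] + (option_idx,) + base[pos + 1 :]
        rest = sum(
            instance.slots[i].options[x - 1].mw
            for i, x in enumerate(combo)
            if i != pos
        )
        new_w = round(instance.target_mw - rest, spec.decimals)
        if new_w <= 0:
            continue
        slot = instance.slots[pos]
        old = slot.options[option_idx - 1]
        new_options = list(slot.options)
        new_options[option_idx - 1] = SideChainOption(
            id=old.id, mw=float(new_w), prob=old.prob, smiles=old.smiles
        )
        new_slots = list(instance.slots)
        new_slots[pos] = PositionSlot(index=slot.index, options=tuple(new_options))
        instance = CsccpInstance(
            slots=tuple(new_slots), target_mw=instance.target_mw, R=R, D=spec.decimals
        )
        planted.append(combo)
    return instance, planted


def precision_adversarial_instance(seed: int, R: int = 1) -> CsccpInstance:
    """Instance where whole-Dalton truncation is maximally misleading.

    Three positions, three chains each; within a position all chains share
    the same integer mass and differ only in the sixth decimal place, so all
    27 assignments collapse into one truncated weight cell.  The target is
    the exact mass of the *least* probable assignment, and every one of the
    26 decoys outranks it by probability product.  The iterative solver's
    first pass (rank budget ``10 R``) therefore cannot see the true match
    and must escalate — by construction it needs at least two passes.
    """
    rng = np.random.default_rng(seed)
    bases = rng.integers(10, 41, size=3)
    micro = (1e-6, 2e-6, 4e-6)  # distinct sixth-decimal offsets; (4,4,4) sum unique
    probs = (0.5, 0.3, 0.2)
    slots = []
    for i in range(3):
        options = tuple(
            SideChainOption(
                id=f"p{i + 1}c{j + 1}",
                mw=float(bases[i]) + micro[j],
                prob=probs[j],
            )
            for j in range(3)
        )
        slots.append(PositionSlot(index=i + 1, options=options))
    # target = exact mass of the all-third-choice assignment, summed in slot
    # order to match the solvers' accumulation
    target = 0.0
    for slot in slots:
        target += slot.options[2].mw
    return CsccpInstance(slots=tuple(slots), target_mw=target, R=R, D=6)


def worked_example_instance(R: int = 2) -> CsccpInstance:
    """The small three-position demonstration instance used throughout the
    docs: two side chains per position, masses [[15,17],[17,62],[17,62]] Da,
    probabilities [[0.2,0.8],[0.8,0.2],[0.2,0.8]].

    The target is 96 Da — the only total-mass class realized by exactly two
    assignments, whose products are 0.512 and 0.032.
    """
    data = [
        ((15.0, 0.2), (17.0, 0.8)),
        ((17.0, 0.8), (62.0, 0.2)),
        ((17.0, 0.2), (62.0, 0.8)),
    ]
    slots = tuple(
        PositionSlot(
            index=i + 1,
            options=tuple(
                SideChainOption(id=f"p{i + 1}c{j + 1}", mw=mw, prob=p)
                for j, (mw, p) in enumerate(pairs)
            ),
        )
        for i, pairs in enumerate(data)
    )
    return CsccpInstance(slots=slots, target_mw=96.0, R=R, D=2)


def catalog_from_instance(
    instance: CsccpInstance, scaffold_id: str = "S1", position_set_id: str = "PS1"
) -> PositionSetCatalog:
    """Wrap a single instance's slots as a one-scaffold catalog."""
    catalog = PositionSetCatalog(mass_decimals=instance.D)
    catalog.add(Scaffold(scaffold_id=scaffold_id, position_sets={position_set_id: instance.slots}))
    return catalog


def synthetic_catalog(
    position_set_counts: Sequence[int],
    seed: int = 0,
    n: int = 2,
    K: int = 2,
    decimals: int = 2,
) -> PositionSetCatalog:
    """Catalog with one scaffold per entry of ``position_set_counts``, each
    carrying that many small random position sets — sized for exercising job
    scheduling, not chemistry."""
    catalog = PositionSetCatalog(mass_decimals=decimals)
    counter = itertools.count()
    for s_idx, n_sets in enumerate(position_set_counts, start=1):
        if n_sets < 1:
            raise ValueError("each scaffold needs >= 1 position set")
        sets = {}
        for p_idx in range(1, n_sets + 1):
            spec = GeneratorSpec(seed=seed + next(counter), n=n, K=K, decimals=decimals)
            rng = np.random.default_rng(spec.seed)
            sets[f"PS{p_idx}"] = tuple(_draw_slots(spec, rng))
        catalog.add(Scaffold(scaffold_id=f"S{s_idx}", position_sets=sets))
    return catalog
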