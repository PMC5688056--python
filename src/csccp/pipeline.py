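"""Orchestration: many solver runs, merged probability-ranked reports.

One structure-elucidation run is a grid of solver jobs — every (seed
scaffold, position set, target MW) triple gets its own instance, so a
library with scaffolds carrying ``N_k`` position sets each and ``N_p``
target masses yields ``N_p * sum(N_k)`` jobs.  Results are pooled two ways:

* per ``(scaffold, target MW)``, merging all of that scaffold's position
  sets — the ranking a chemist reads per scaffold hypothesis;
* per target MW across scaffolds — one merged list per observed mass.

Candidates from different position sets are deliberately kept distinct even
when they assemble to the same string (each is a different substitution
hypothesis); pass ``dedupe=True`` to collapse them keeping the best rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .model import CsccpInstance, PositionSetCatalog, PositionSlot, Scaffold
from . import solvers

__all__ = [
    "ElucidationJob",
    "RankedCandidate",
    "ElucidationReport",
    "enumerate_jobs",
    "run_elucidation",
    "assemble_structure",
    "match_reference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElucidationJob:
    """One solver invocation: a scaffold's position set against one target MW."""

    scaffold_id: str
    position_set_id: str
    target_mw: float
    instance: CsccpInstance


@dataclass(frozen=True)
class RankedCandidate:
    """One ranked structure hypothesis within a pool."""

    rank: int
    scaffold_id: str
    position_set_id: str
    target_mw: float
    assignment: str  # canonical "pos=chain|pos=chain" text
    product: float
    total_sidechain_mw: float
    assembled: str = ""


@dataclass
class ElucidationReport:
    """Pooled, ranked candidates plus run metadata.

    ``pools`` maps ``(scaffold_id, target_mw)`` to its ranked list;
    ``global_pools`` maps ``target_mw`` to the cross-scaffold merge.
    """

    pools: dict[tuple[str, float], list[RankedCandidate]] = field(default_factory=dict)
    global_pools: dict[float, list[RankedCandidate]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def all_candidates(self) -> list[RankedCandidate]:
        return [c for pool in self.pools.values() for c in pool]


def enumerate_jobs(
    catalog: PositionSetCatalog,
    mw_list: Sequence[float],
    R: int = 10,
    D: int = 6,
) -> list[ElucidationJob]:
    """Expand the full job grid: every target MW against every position set
    of every scaffold."""
    if len(catalog) == 0:
        raise ValueError("empty catalog: no scaffolds to elucidate")
    if not mw_list:
        raise ValueError("empty target MW list")
    jobs = []
    for mw in mw_list:
        for scaffold in catalog:
            for set_id, slots in scaffold.position_sets.items():
                jobs.append(
                    ElucidationJob(
                        scaffold_id=scaffold.scaffold_id,
                        position_set_id=set_id,
                        target_mw=mw,
                        instance=CsccpInstance(slots=slots, target_mw=mw, R=R, D=D),
                    )
                )
    return jobs


def _canonical_assignment(instance: CsccpInstance, assignment: tuple[int, ...]) -> str:
    mapping = {
        slot.index: slot.options[x - 1].id for slot, x in zip(instance.slots, assignment)
    }
    return "|".join(f"{idx}={mapping[idx]}" for idx in sorted(mapping))


def assemble_structure(
    scaffold: Scaffold,
    slots: Sequence[PositionSlot],
    assignment: Sequence[int],
) -> str:
    """Substitute the chosen side chains into the scaffold's template.

    Each position ``i`` must appear as a placeholder ``R<i>`` in the
    template; the placeholder is replaced with the chosen chain's SMILES
    fragment (falling back to its id).  Without a template the canonical
    textual form ``scaffold|pos=chain|...`` is returned.
    """
    chosen = {}
    for slot, x in zip(slots, assignment):
        opt = slot.options[x - 1]
        chosen[slot.index] = opt.smiles or opt.id
    if not scaffold.template:
        parts = [f"{idx}={slot.options[x - 1].id}" for slot, x, idx in
                 ((s, a, s.index) for s, a in zip(slots, assignment))]
        ordered = sorted(zip((s.index for s in slots), parts))
        return scaffold.scaffold_id + "|" + "|".join(p for _, p in ordered)
    text = scaffold.template
    for idx in sorted(chosen, reverse=True):  # R12 before R1
        placeholder = f"R{idx}"
        if placeholder not in text:
            raise ValueError(
                f"scaffold {scaffold.scaffold_id!r}: template lacks placeholder {placeholder}"
            )
        text = text.replace(placeholder, chosen[idx])
    return text


_SOLVER_DISPATCH: dict[str, Callable] = {
    "bf": lambda inst, R, tol: solvers.brute_force_topR(inst, tol=tol, R=R),
    "dp": lambda inst, R, tol: solvers.dp_solve(inst, R=R),
    "idp": lambda inst, R, tol: solvers.idp_solve(inst, R=R, tol=tol),
}


def run_elucidation(
    jobs: Sequence[ElucidationJob],
    algorithm: str = "idp",
    R: int | None = None,
    tol: float = solvers.DEFAULT_MASS_TOL,
    catalog: PositionSetCatalog | None = None,
    dedupe: bool = False,
) -> ElucidationReport:
    """Run the chosen solver over every job and build the pooled report.

    Per-job solver failures are recorded under ``metadata['errors']`` and do
    not abort the run.  Ties are broken by (scaffold, position set,
    assignment) so reports are byte-identical across runs.
    """
    if algorithm not in _SOLVER_DISPATCH:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected bf, dp or idp")
    solve = _SOLVER_DISPATCH[algorithm]
    raw: dict[tuple[str, float], list] = {}
    errors: list[str] = []
    loop_counts: list[int] = []
    for job in jobs:
        r = job.instance.R if R is None else R
        try:
            result = solve(job.instance, r, tol)
        except Exception as exc:  # noqa: BLE001 - per-job isolation is the contract
            errors.append(
                f"{job.scaffold_id}/{job.position_set_id}@{job.target_mw}: {exc}"
            )
            logger.warning("job failed: %s", errors[-1])
            continue
        if result.loop_count is not None:
            loop_counts.append(result.loop_count)
        pool_key = (job.scaffold_id, job.target_mw)
        bucket = raw.setdefault(pool_key, [])
        for entry in result.top:
            scaffold = catalog.get(job.scaffold_id) if catalog is not None else None
            if scaffold is not None and scaffold.template:
                assembled = assemble_structure(
                    scaffold, job.instance.slots, entry.assignment
                )
            else:
                assembled = (
                    job.scaffold_id
                    + "|"
                    + _canonical_assignment(job.instance, entry.assignment)
                )
            bucket.append(
                (
                    entry.product,
                    job.position_set_id,
                    _canonical_assignment(job.instance, entry.assignment),
                    entry.exact_mass,
                    assembled,
                )
            )

    report = ElucidationReport(
        metadata={
            "algorithm": algorithm,
            "R": R,
            "tol": tol,
            "n_jobs": len(jobs),
            "errors": errors,
            "loop_counts": loop_counts,
            "dedupe": dedupe,
        }
    )
    for (scaffold_id, mw), bucket in raw.items():
        bucket.sort(key=lambda c: (-c[0], c[1], c[2]))
        if dedupe:
            seen: set[str] = set()
            bucket = [c for c in bucket if not (c[4] in seen or seen.add(c[4]))]
        report.pools[(scaffold_id, mw)] = [
            RankedCandidate(
                rank=i,
                scaffold_id=scaffold_id,
                position_set_id=ps,
                target_mw=mw,
                assignment=assign,
                product=product,
                total_sidechain_mw=mass,
                assembled=assembled,
            )
            for i, (product, ps, assign, mass, assembled) in enumerate(bucket, start=1)
        ]
    # cross-scaffold merge per target MW
    by_mw: dict[float, list[RankedCandidate]] = {}
    for (scaffold_id, mw), pool in report.pools.items():
        by_mw.setdefault(mw, []).extend(pool)
    for mw, cands in by_mw.items():
        cands.sort(key=lambda c: (-c.product, c.scaffold_id, c.position_set_id, c.assignment))
        report.global_pools[mw] = [
            RankedCandidate(
                rank=i,
                scaffold_id=c.scaffold_id,
                position_set_id=c.position_set_id,
                target_mw=c.target_mw,
                assignment=c.assignment,
                product=c.product,
                total_sidechain_mw=c.total_sidechain_mw,
                assembled=c.assembled,
            )
            for i, c in enumerate(cands, start=1)
        ]
    return report


def match_reference(
    report: ElucidationReport, references: Sequence[str]
) -> list[tuple[str, int | None]]:
    """Best (lowest) per-scaffold-pool rank for each reference structure
    string, or ``None`` when no pool contains it."""
    out = []
    for ref in references:
        best: int | None = None
        for pool in report.pools.values():
            for cand in pool:
                if cand.assembled == ref and (best is None or cand.rank < best):
                    best = cand.rank
        out.append((ref, best))
    return out
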