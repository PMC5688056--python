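"""Readers and writers for the tool's tabular formats.

Side-chain libraries are UTF-8 TSV (TSV so SMILES commas need no escaping)
with the header::

    scaffold_id  position_set_id  position_index  sidechain_id  smiles  mw  prob

The last column may instead be named ``count``; raw occurrence counts are
then normalized to probabilities per position at load time.  Target-MW
lists are plain text, one neutral mass per line, ``#`` comments and blank
lines allowed.  Masses are parsed from their decimal strings so the
printed precision (number of decimal places) is known exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .model import (
    PositionSetCatalog,
    PositionSlot,
    Scaffold,
    SideChainOption,
    normalize_counts_to_probs,
)
from .pipeline import ElucidationReport, RankedCandidate
from . import solvers

__all__ = [
    "RunConfig",
    "read_sidechain_library",
    "write_sidechain_library",
    "read_mw_list",
    "write_report_tsv",
    "write_report_json",
    "read_report_json",
]

logger = logging.getLogger(__name__)

_LIBRARY_COLUMNS = (
    "scaffold_id",
    "position_set_id",
    "position_index",
    "sidechain_id",
    "smiles",
    "mw",
)

_REPORT_COLUMNS = (
    "rank",
    "scaffold_id",
    "position_set_id",
    "target_mw",
    "product",
    "total_sidechain_mw",
    "assignment",
    "assembled",
)


@dataclass
class RunConfig:
    """Runtime knobs shared by the CLI commands.

    ``R`` is the number of reported solutions (10 covers the observed ranks
    of validated natural-product structures), ``D`` the mass decimals kept
    by the scaled DP, ``mass_tol`` the exact-mass match window in Da.
    """

    algorithm: str = "idp"
    R: int = 10
    D: int = 6
    mass_tol: float = solvers.DEFAULT_MASS_TOL
    dedupe: bool = False
    bf_guard: int = solvers.BRUTE_FORCE_GUARD

    def __post_init__(self) -> None:
        if self.algorithm not in ("bf", "dp", "idp"):
            raise ValueError(f"algorithm must be bf, dp or idp, got {self.algorithm!r}")
        if self.R < 1:
            raise ValueError(f"R must be >= 1, got {self.R}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.mass_tol < 0:
            raise ValueError(f"mass_tol must be >= 0, got {self.mass_tol}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path}: expected a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)


def _decimals_of(text: str) -> int:
    if "." in text:
        return len(text.split(".", 1)[1].rstrip())
    return 0


def read_sidechain_library(path: str | Path) -> PositionSetCatalog:
    """Load and validate a side-chain library TSV into a scaffold catalog.

    Zero-probability (or zero-count) side chains are dropped; per-position
    probabilities that do not sum to 1 are accepted with a warning.  All
    errors carry 1-based line numbers.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            rows.append((lineno, row))
    if not rows:
        raise ValueError(f"{path}: no rows")
    header_line, header = rows[0]
    header = [h.strip() for h in header]
    if tuple(header[:6]) != _LIBRARY_COLUMNS or len(header) != 7 or header[6] not in (
        "prob",
        "count",
    ):
        raise ValueError(
            f"{path}:{header_line}: bad header; expected "
            f"{' '.join(_LIBRARY_COLUMNS)} prob|count"
        )
    value_kind = header[6]

    # (scaffold, set, position) -> list of (lineno, id, smiles, mw, value)
    grouped: dict[tuple[str, str, int], list] = {}
    seen_chains: set[tuple[str, str, int, str]] = set()
    max_decimals = 0
    for lineno, row in rows[1:]:
        if len(row) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
        scaffold_id, set_id, pos_text, chain_id, smiles, mw_text, value_text = (
            c.strip() for c in row
        )
        try:
            pos = int(pos_text)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad position index {pos_text!r}") from None
        try:
            mw = float(mw_text)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad molecular weight {mw_text!r}") from None
        try:
            value = float(value_text)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: bad {value_kind} value {value_text!r}"
            ) from None
        if not scaffold_id or not set_id or not chain_id:
            raise ValueError(f"{path}:{lineno}: empty identifier column")
        if mw <= 0:
            raise ValueError(f"{path}:{lineno}: molecular weight must be > 0, got {mw}")
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative {value_kind} {value}")
        key = (scaffold_id, set_id, pos, chain_id)
        if key in seen_chains:
            raise ValueError(
                f"{path}:{lineno}: duplicate side chain {chain_id!r} at "
                f"{scaffold_id}/{set_id} position {pos}"
            )
        seen_chains.add(key)
        max_decimals = max(max_decimals, _decimals_of(mw_text))
        grouped.setdefault((scaffold_id, set_id, pos), []).append(
            (lineno, chain_id, smiles, mw, value)
        )

    # assemble scaffolds preserving file order
    scaffold_sets: dict[str, dict[str, dict[int, list]]] = {}
    for (scaffold_id, set_id, pos), options in grouped.items():
        scaffold_sets.setdefault(scaffold_id, {}).setdefault(set_id, {})[pos] = options

    catalog = PositionSetCatalog(mass_decimals=max_decimals)
    for scaffold_id, sets in scaffold_sets.items():
        position_sets = {}
        for set_id, positions in sets.items():
            slots = []
            for pos in sorted(positions):
                options = positions[pos]
                if value_kind == "count":
                    counts = {chain_id: value for _, chain_id, _, _, value in options}
                    try:
                        probs = normalize_counts_to_probs(counts)
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: {scaffold_id}/{set_id} position {pos}: {exc}"
                        ) from None
                else:
                    probs = {
                        chain_id: value for _, chain_id, _, _, value in options if value > 0
                    }
                    if not probs:
                        raise ValueError(
                            f"{path}: {scaffold_id}/{set_id} position {pos}: "
                            "all probabilities are zero"
                        )
                    total = sum(probs.values())
                    if abs(total - 1.0) > 1e-6:
                        logger.warning(
                            "%s: %s/%s position %d: probabilities sum to %.6g, not 1 "
                            "(accepted as-is)",
                            path,
                            scaffold_id,
                            set_id,
                            pos,
                            total,
                        )
                kept = tuple(
                    SideChainOption(id=chain_id, mw=mw, prob=probs[chain_id], smiles=smiles)
                    for _, chain_id, smiles, mw, _ in options
                    if chain_id in probs
                )
                slots.append(PositionSlot(index=pos, options=kept))
            position_sets[set_id] = tuple(slots)
        catalog.add(Scaffold(scaffold_id=scaffold_id, position_sets=position_sets))
    return catalog


def write_sidechain_library(catalog: PositionSetCatalog, path: str | Path) -> None:
    """Write a catalog back to the library TSV format (prob column)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LIBRARY_COLUMNS + ("prob",))
        for scaffold in catalog:
            for set_id, slots in scaffold.position_sets.items():
                for slot in slots:
                    for opt in slot.options:
                        writer.writerow(
                            [
                                scaffold.scaffold_id,
                                set_id,
                                slot.index,
                                opt.id,
                                opt.smiles,
                                repr(opt.mw) if opt.mw != int(opt.mw) else int(opt.mw),
                                repr(opt.prob),
                            ]
                        )


def read_mw_list(path: str | Path) -> list[float]:
    """Load a target-MW list: one positive decimal per line, ``#`` comments
    and blank lines skipped, errors reported with line numbers."""
    path = Path(path)
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                value = float(text)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: not a number: {text!r}") from None
            if value <= 0:
                raise ValueError(f"{path}:{lineno}: target MW must be > 0, got {value}")
            out.append(value)
    if not out:
        raise ValueError(f"{path}: no target MWs found")
    return out


def write_report_tsv(report: ElucidationReport, path: str | Path) -> None:
    """Per-scaffold pools as TSV, one row per ranked candidate."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPORT_COLUMNS)
        for key in sorted(report.pools, key=lambda k: (k[1], k[0])):
            for c in report.pools[key]:
                writer.writerow(
                    [
                        c.rank,
                        c.scaffold_id,
                        c.position_set_id,
                        repr(c.target_mw),
                        repr(c.product),
                        repr(c.total_sidechain_mw),
                        c.assignment,
                        c.assembled,
                    ]
                )


def write_report_json(report: ElucidationReport, path: str | Path) -> None:
    """Full report (both pooling conventions plus metadata) as JSON."""
    payload = {
        "metadata": report.metadata,
        "pools": [
            {
                "scaffold_id": scaffold_id,
                "target_mw": mw,
                "candidates": [asdict(c) for c in pool],
            }
            for (scaffold_id, mw), pool in sorted(
                report.pools.items(), key=lambda kv: (kv[0][1], kv[0][0])
            )
        ],
        "global_pools": [
            {
                "target_mw": mw,
                "candidates": [asdict(c) for c in pool],
            }
            for mw, pool in sorted(report.global_pools.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report_json(path: str | Path) -> ElucidationReport:
    """Inverse of :func:`write_report_json`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    report = ElucidationReport(metadata=payload.get("metadata", {}))
    for pool in payload.get("pools", []):
        key = (pool["scaffold_id"], pool["target_mw"])
        report.pools[key] = [RankedCandidate(**c) for c in pool["candidates"]]
    for pool in payload.get("global_pools", []):
        report.global_pools[pool["target_mw"]] = [
            RankedCandidate(**c) for c in pool["candidates"]
        ]
    return report
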