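"""Structural coverage of the reference and pLDDT-based disorder statistics.

Coverage counts, per reference position, the number of distinct
*structures* (not chains) with an aligned residue there - a homodimer
covering a position with both chains contributes one.  Disorder is defined
on the predicted model: a position is disordered when the mean atomic
pLDDT of its residue falls below a threshold (default 50; 70 is a common
stricter choice and is supported via the ``threshold`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ResidueCategory, StructureModel, StructureSource
from .mutation_data import MutationRecord
from .renumbering import ResidueMap

__all__ = [
    "CoverageProfile",
    "DisorderProfile",
    "compute_coverage",
    "compute_disorder",
    "mutations_in_disorder",
    "round_half_up",
    "DISORDER_PLDDT_THRESHOLD",
]

DISORDER_PLDDT_THRESHOLD = 50.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), matching how
    percentages are conventionally reported."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CoverageProfile:
    """Per-position structural coverage of the reference sequence."""

    length: int
    per_position_count: np.ndarray  # int array, index 0 = position 1
    covered_fraction: float
    uncovered_segments: list[tuple[int, int]]  # 1-based closed intervals

    def is_covered(self, position: int) -> bool:
        return bool(self.per_position_count[position - 1] > 0)


@dataclass
class DisorderProfile:
    """Disordered reference positions from predicted-model confidence."""

    length: int
    disordered_positions: set[int] = field(default_factory=set)
    disorder_fraction: float = 0.0
    method: str = "plddt_threshold"
    threshold: float = DISORDER_PLDDT_THRESHOLD


def _zero_segments(counts: np.ndarray) -> list[tuple[int, int]]:
    segments: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(counts):
        if c == 0 and start is None:
            start = i + 1
        elif c > 0 and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(counts)))
    return segments


def compute_coverage(maps: Sequence[ResidueMap], length: int) -> CoverageProfile:
    """Coverage profile from residue maps of any number of structures.

    Maps belonging to the same ``structure_id`` are merged first so each
    structure contributes at most 1 to any position's count.
    """
    if length < 1:
        raise ValueError("reference length must be >= 1")
    counts = np.zeros(length, dtype=int)
    by_structure: dict[str, set[int]] = {}
    for rm in maps:
        positions = rm.uniprot_positions()
        bad = [p for p in positions if p < 1 or p > length]
        if bad:
            raise ValueError(
                f"residue map {rm.structure_id}/{rm.chain_id} contains positions "
                f"outside [1, {length}]: {sorted(bad)[:5]}"
            )
        by_structure.setdefault(rm.structure_id, set()).update(positions)
    for positions in by_structure.values():
        for p in positions:
            counts[p - 1] += 1
    covered = int(np.count_nonzero(counts))
    return CoverageProfile(
        length=length,
        per_position_count=counts,
        covered_fraction=covered / length,
        uncovered_segments=_zero_segments(counts),
    )


def compute_disorder(
    predicted_model: StructureModel,
    residue_map: ResidueMap,
    threshold: float = DISORDER_PLDDT_THRESHOLD,
    length: int | None = None,
) -> DisorderProfile:
    """Disordered positions of the reference from a predicted model.

    A position is disordered iff the mean atomic pLDDT of its residue is
    below ``threshold``.  ``length`` defaults to the reference length
    implied by the largest mapped position.
    """
    if predicted_model.source is not StructureSource.PREDICTED:
        raise ValueError("disorder is defined on predicted models only")
    index = {
        (r.chain_id, r.auth_seq_num, r.insertion_code): r
        for r in predicted_model.iter_residues()
        if r.category is ResidueCategory.PROTEIN
    }
    disordered: set[int] = set()
    max_pos = 0
    for (seq_num, icode), pos in residue_map.entries.items():
        res = index.get((residue_map.chain_id, seq_num, icode))
        if res is None:
            continue
        max_pos = max(max_pos, pos)
        if res.mean_temp_factor() < threshold:
            disordered.add(pos)
    length = length if length is not None else max_pos
    if length < 1:
        raise ValueError("cannot determine reference length")
    return DisorderProfile(
        length=length,
        disordered_positions=disordered,
        disorder_fraction=len(disordered) / length,
        threshold=threshold,
    )


def mutations_in_disorder(
    records: Sequence[MutationRecord], disorder: DisorderProfile
) -> tuple[int, float]:
    """Count unique mutations at disordered positions.

    Returns ``(n_in_disorder, percent_of_unique)`` with the percentage
    rounded half-up to 1 decimal.  ``records`` must already be
    deduplicated (one record per unique substitution).
    """
    if not records:
        raise ValueError("percentage undefined for an empty record list")
    keys = {r.key for r in records}
    if len(keys) != len(records):
        raise ValueError("records must be unique substitutions (deduplicate first)")
    n = sum(1 for r in records if r.position in disorder.disordered_positions)
    pct = round_half_up(100.0 * n / len(records), 1)
    return n, pct
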