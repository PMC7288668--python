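"""Family-level frequency tables over a set of zipper registers:
composition at the a and d interface positions, the per-heptad placement
of a-position asparagines, and the per-heptad tally of g<->e' pair types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .domains import MAX_HEPTADS
from .zipper import (
    PAIR_CATEGORIES,
    ZipperRegister,
    call_ge_pair,
    classify_a_residue,
    classify_d_residue,
)

A_CATEGORIES = ("asn", "hydrophobic", "charged", "other")
D_CATEGORIES = ("leucine", "other_hydrophobic", "other")


@dataclass(frozen=True)
class PositionCompositionTable:
    """Counts and percentages of residue classes at one interface
    position (a or d) over every defined slot in the family."""

    position: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n_defined: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.position,
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [self.percentages[c] for c in self.counts],
            }
        )


@dataclass(frozen=True)
class AsnHeptadHistogram:
    """Where a-position asparagines fall along the zipper: count per
    heptad index and percentage of all a-position Asn."""

    counts: dict[int, int]
    percentages: dict[int, float]
    n_asn: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "heptad": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [self.percentages[n] for n in self.counts],
            }
        )


@dataclass(frozen=True)
class GEPairHistogram:
    """Per-heptad-index counts of the four complete g<->e' pair types and
    of incomplete pairs.  'Total pairs at Ln' counts complete pairs only.
    """

    counts: dict[int, dict[str, int]]

    def total_complete(self, n: int) -> int:
        return sum(v for c, v in self.counts[n].items() if c != "incomplete")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in sorted(self.counts):
            row = {"heptad": n, **self.counts[n], "total_complete": self.total_complete(n)}
            rows.append(row)
        return pd.DataFrame(rows)


def _require_registers(registers: Sequence[ZipperRegister]) -> None:
    if len(registers) == 0:
        raise ValueError("empty register family")


def position_composition(
    registers: Sequence[ZipperRegister], position: str
) -> PositionCompositionTable:
    """Residue-class composition at slot a or d across the family.

    The denominator is the number of heptads (over all proteins) whose
    slot at the position is defined; percentages sum to 100.
    """
    if position not in ("a", "d"):
        raise ValueError("position must be 'a' or 'd'")
    _require_registers(registers)
    classifier = classify_a_residue if position == "a" else classify_d_residue
    categories = A_CATEGORIES if position == "a" else D_CATEGORIES
    counts = {c: 0 for c in categories}
    for reg in registers:
        for h in reg.heptads:
            cls = classifier(h.slots[position])
            if cls is not None:
                counts[cls] += 1
    n_defined = sum(counts.values())
    percentages = {
        c: (100.0 * v / n_defined if n_defined else 0.0) for c, v in counts.items()
    }
    return PositionCompositionTable(
        position=position, counts=counts, percentages=percentages, n_defined=n_defined
    )


def asn_histogram(registers: Sequence[ZipperRegister]) -> AsnHeptadHistogram:
    """Distribution of a-position asparagines over heptad indices; an
    all-zero table when the family has none."""
    _require_registers(registers)
    counts = {n: 0 for n in range(MAX_HEPTADS)}
    for reg in registers:
        for h in reg.heptads:
            if h.slots["a"] == "N":
                counts[h.index] += 1
    n_asn = sum(counts.values())
    percentages = {
        n: (100.0 * v / n_asn if n_asn else 0.0) for n, v in counts.items()
    }
    return AsnHeptadHistogram(counts=counts, percentages=percentages, n_asn=n_asn)


def ge_histogram(registers: Sequence[ZipperRegister]) -> GEPairHistogram:
    """Per-heptad-index tally of g<->e' pair calls across the family."""
    _require_registers(registers)
    counts = {n: {c: 0 for c in PAIR_CATEGORIES} for n in range(MAX_HEPTADS)}
    for reg in registers:
        for h in reg.heptads:
            call = call_ge_pair(h)
            counts[h.index][call.category] += 1
    return GEPairHistogram(counts=counts)
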