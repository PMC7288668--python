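"""bZIP domain detection and ProtParam-style physicochemical properties.

The basic (DNA-binding) region of a plant bZIP follows the 18-residue
grammar N-X7-R/K-X9; the adjacent leucine zipper is a leucine-periodic
helix (canonically L-X6-L-X6-L, though family surveys report zippers of
as few as two heptads).  This module locates both signals with exact
pattern matching and computes per-protein length, average molecular
weight and isoelectric point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .records import ProteinRecord

logger = logging.getLogger(__name__)

BASIC_REGION_LEN = 18
#: N, any 7, R or K, any 9 — overlapping matches found via lookahead.
_BASIC_RE = re.compile(r"(?=(N.{7}[RK].{9}))", flags=0)

#: Heptads are capped at L0..L9.
MAX_HEPTADS = 10

# Bjellqvist pKa values (the ExPASy set) for the Henderson-Hasselbalch
# charge model used by the pI bisection.
_POSITIVE_PKA = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKA = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

_WATER_DA = 18.0153


@dataclass(frozen=True)
class BZipDomain:
    """A located bZIP domain: basic-region bounds plus the zipper anchor
    (index of the leucine at slot d of heptad L0) and the end of the
    residues assigned to heptads."""

    protein_id: str
    basic_start: int
    basic_end: int
    anchor_leu: int
    zipper_end: int
    truncated_l0: bool = False

    def validate(self, seq: str) -> None:
        if not (0 <= self.basic_start < self.basic_end <= self.anchor_leu
                < self.zipper_end <= len(seq)):
            raise ValueError(
                f"{self.protein_id}: inconsistent domain coordinates "
                f"({self.basic_start}, {self.basic_end}, {self.anchor_leu}, "
                f"{self.zipper_end}) for length {len(seq)}"
            )
        if seq[self.anchor_leu] != "L":
            raise ValueError(
                f"{self.protein_id}: anchor residue at {self.anchor_leu} "
                f"is {seq[self.anchor_leu]!r}, expected 'L'"
            )


@dataclass(frozen=True)
class ProteinProps:
    """Length (residues), molecular weight (kDa, average isotopic masses)
    and isoelectric point.  mw/pi are None (undefined) when the sequence
    contains X."""

    length: int
    mw: float | None
    pi: float | None


def find_basic_region(seq: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) matches of the basic-region grammar
    N-X7-[RK]-X9, left to right, as 0-based half-open 18-residue spans."""
    return [(m.start(), m.start() + BASIC_REGION_LEN) for m in _BASIC_RE.finditer(seq)]


def find_zipper_anchor(seq: str, from_pos: int) -> int | None:
    """First leucine at or after ``from_pos`` that can start a zipper.

    An L qualifies when a second heptad is available: either another L
    exactly 7 residues downstream, or at least 7 residues following it
    (so heptad L1 is fully populated).  Returns None when no L qualifies.
    """
    n = len(seq)
    for i in range(max(from_pos, 0), n):
        if seq[i] != "L":
            continue
        if (i + 7 < n and seq[i + 7] == "L") or (n - (i + 1) >= 7):
            return i
    return None


def scan_protein(rec: ProteinRecord) -> BZipDomain | None:
    """Locate the bZIP domain of a protein, or None.

    The leftmost basic-region match that is followed by a zipper anchor
    wins; the anchor is the first leucine at or after the end of the
    18-residue match (the basic region itself may contain leucines that
    are not part of the zipper).  Heptads run from four residues before
    the anchor to the sequence end or the end of L9, whichever is first.
    """
    seq = rec.sequence
    matches = find_basic_region(seq)
    chosen: BZipDomain | None = None
    for k, (bs, be) in enumerate(matches):
        anchor = find_zipper_anchor(seq, be)
        if anchor is None:
            continue
        if chosen is None:
            zipper_end = min(len(seq), anchor - 4 + 7 * MAX_HEPTADS)
            chosen = BZipDomain(
                protein_id=rec.id,
                basic_start=bs,
                basic_end=be,
                anchor_leu=anchor,
                zipper_end=zipper_end,
                truncated_l0=anchor < 4,
            )
        else:
            logger.debug("%s: alternate basic-region match at %d ignored", rec.id, bs)
    if chosen is not None:
        chosen.validate(seq)
    return chosen


def net_charge(seq: str, ph: float) -> float:
    """Net charge of a peptide at a given pH under the Henderson-
    Hasselbalch model with the Bjellqvist pKa set (free termini plus the
    D, E, C, Y, H, K, R side chains)."""
    charge = 1.0 / (1.0 + 10 ** (ph - _POSITIVE_PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_NEGATIVE_PKA["Cterm"] - ph))
    for res, pka in _POSITIVE_PKA.items():
        if len(res) == 1:
            charge += seq.count(res) / (1.0 + 10 ** (ph - pka))
    for res, pka in _NEGATIVE_PKA.items():
        if len(res) == 1:
            charge -= seq.count(res) / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, positive at pH 0 and
    negative at pH 14 (the free termini guarantee both), so the root is
    unique.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight_kda(seq: str) -> float:
    """Average molecular weight in kDa (sum of average residue masses
    plus one water)."""
    return ProteinAnalysis(seq).molecular_weight() / 1000.0


def compute_props(rec: ProteinRecord) -> ProteinProps:
    """Length, MW (kDa) and pI of a protein; MW/pI are undefined (None)
    when the sequence contains the unknown residue X."""
    seq = rec.sequence
    if "X" in seq:
        logger.warning("%s: sequence contains X; mw and pi undefined", rec.id)
        return ProteinProps(length=len(seq), mw=None, pi=None)
    return ProteinProps(
        length=len(seq),
        mw=molecular_weight_kda(seq),
        pi=isoelectric_point(seq),
    )
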