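"""Exact-word scanning of promoter sequences for ACGT-core cis-elements.

bZIP dimers bind palindromic hexamers built around an ACGT core: the
A-box (TACGTA), G-box (CACGTG) and C-box (GACGTC).  Promoters are taken
as the window upstream of the translation start (sequence end by
convention); hit offsets are negative 1-based upstream coordinates of
the match's 5'-most base (-1 = the base immediately upstream of ATG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .records import DnaRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_WINDOW = 1500


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BoxDefinition:
    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"box consensus must be a non-empty ACGT word: {self.consensus!r}")

    @property
    def palindromic(self) -> bool:
        return self.consensus == reverse_complement(self.consensus)


A_BOX = BoxDefinition("A-box", "TACGTA")
G_BOX = BoxDefinition("G-box", "CACGTG")
C_BOX = BoxDefinition("C-box", "GACGTC")
ACGT_CORE = BoxDefinition("ACGT-core", "ACGT")

#: Fig-8a-style default: the three named hexamer boxes; the bare ACGT
#: core is opt-in because it hits far too often to be informative alone.
DEFAULT_BOXES = (A_BOX, G_BOX, C_BOX)


@dataclass(frozen=True)
class PromoterHit:
    promoter_id: str
    box: str
    offset: int
    strand: str


def _find_all(haystack: str, word: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(word, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1  # overlapping occurrences allowed


def scan_promoter(
    rec: DnaRecord,
    boxes: Sequence[BoxDefinition] = DEFAULT_BOXES,
    window: int = DEFAULT_WINDOW,
) -> list[PromoterHit]:
    """Exact-match scan of the final ``window`` nt of a promoter on both
    strands.

    All default consensi are reverse-complement palindromes, so a minus-
    strand match always coincides with a plus-strand one; duplicate hits
    at one position are collapsed to the + strand.  Hits are sorted by
    offset, then box name.
    """
    seq = rec.sequence
    if window < 1:
        raise ValueError("window must be positive")
    if window > len(seq):
        logger.warning(
            "%s: window %d exceeds sequence length %d; scanning available span",
            rec.id, window, len(seq),
        )
    span = seq[-window:]
    span_start = len(seq) - len(span)
    hits: list[PromoterHit] = []
    for box in boxes:
        if len(box.consensus) > len(seq):
            continue
        plus = _find_all(span, box.consensus)
        for p in plus:
            hits.append(PromoterHit(rec.id, box.name, span_start + p - len(seq), "+"))
        rc = reverse_complement(box.consensus)
        minus = _find_all(span, rc)
        plus_set = set(plus)
        for p in minus:
            if box.palindromic and p in plus_set:
                continue  # collapsed onto the + hit
            hits.append(PromoterHit(rec.id, box.name, span_start + p - len(seq), "-"))
    hits.sort(key=lambda h: (h.offset, h.box, h.strand))
    return hits
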