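"""Shared record types for the pipeline.

Coordinates are 0-based half-open everywhere inside the package; report
writers convert to 1-based (proteins) or negative upstream offsets
(promoters) at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

EXPRESSION_KINDS = ("ct", "relative", "normalized")


class AlphabetError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a unique accession.

    The sequence is uppercase over the 20 canonical residues; ``X`` is
    permitted as an unknown-residue placeholder (it disables molecular
    weight and pI downstream).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein record {self.id!r} contains illegal characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DnaRecord:
    """A nucleotide sequence, by convention a promoter whose 3' end is the
    translation start (offset −1 is the last base of the sequence)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("DNA record requires a non-empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"DNA record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"DNA record {self.id!r} contains illegal characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionTable:
    """A gene × sample numeric matrix.

    ``kind`` distinguishes raw qPCR cycle thresholds (``ct``), relative
    expression (fold changes, FPKM and the like) and row-scaled values
    (``normalized``).  Missing values are NaN — never 0, which would be a
    meaningless Ct.
    """

    values: pd.DataFrame
    kind: str = "relative"

    def __post_init__(self) -> None:
        if self.kind not in EXPRESSION_KINDS:
            raise ValueError(f"unknown expression kind {self.kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression table")
        self.values = self.values.astype(float)
        if self.kind == "ct":
            present = self.values.to_numpy()
            present = present[~np.isnan(present)]
            if (present <= 0).any():
                raise ValueError("Ct values must be positive where present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
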