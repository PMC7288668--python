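"""Heptad register assignment and dimerization typing for leucine zippers.

The zipper is partitioned into heptads L0..L9.  L0 covers the four
residues before the anchoring leucine, the leucine itself, and the two
residues after it; within a heptad the slot order is g, a, b, c, d, e, f,
which places the anchor leucine at slot d of L0.  Assignment continues in
consecutive 7-residue windows to the sequence end or L9.

Dimerization propensity is read off the register:

* slot a — asparagine forms the a<->a' polar pocket that favours
  homodimers; I/V/L/M pack the hydrophobic core; R/K/E/D are charged.
* slot d — canonically leucine; I/V/M are the other core hydrophobes.
* the g and e slots flank the interface; when both members of a
  heptad's g<->e' pair are charged (R/K/E/D) the pair is attractive
  (opposite charges, a salt bridge) or repulsive (like charges).

Proteins are then binned into three categories: (I) homodimerizing —
attractive pairs plus an a-position Asn and no repulsive pair; (III)
heterodimerizing — repulsive pairs only; (II) both — everything with a
mixture (or attractive pairs but no Asn); registers with no complete
pair at all are indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domains import MAX_HEPTADS, BZipDomain

SLOT_ORDER = "gabcdef"

BASIC_RESIDUES = frozenset("RK")
ACIDIC_RESIDUES = frozenset("ED")
CHARGED_RESIDUES = BASIC_RESIDUES | ACIDIC_RESIDUES
A_HYDROPHOBIC = frozenset("IVLM")
D_OTHER_HYDROPHOBIC = frozenset("IVM")

PAIR_CATEGORIES = (
    "attractive_basic_acidic",
    "attractive_acidic_basic",
    "repulsive_basic",
    "repulsive_acidic",
    "incomplete",
)
DIMER_CATEGORIES = ("I_homodimer", "II_both", "III_heterodimer", "indeterminate")


@dataclass(frozen=True)
class Heptad:
    """One 7-residue repeat Ln; absent slots (truncated L0 or a trailing
    partial heptad) are None."""

    index: int
    slots: dict[str, str | None]

    def __post_init__(self) -> None:
        if not 0 <= self.index < MAX_HEPTADS:
            raise ValueError(f"heptad index {self.index} out of range 0..9")
        if set(self.slots) != set(SLOT_ORDER):
            raise ValueError("heptad must define all of g,a,b,c,d,e,f (None allowed)")
        if all(v is None for v in self.slots.values()):
            raise ValueError("heptad has no defined slot")

    def defined(self) -> str:
        return "".join(self.slots[s] for s in SLOT_ORDER if self.slots[s] is not None)


@dataclass(frozen=True)
class ZipperRegister:
    protein_id: str
    heptads: tuple[Heptad, ...]
    truncated_l0: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.heptads) <= MAX_HEPTADS:
            raise ValueError("register must hold between 1 and 10 heptads")
        for n, h in enumerate(self.heptads):
            if h.index != n:
                raise ValueError("heptad indices must be consecutive from 0")

    @property
    def n_heptads(self) -> int:
        return len(self.heptads)

    def sequence(self) -> str:
        """Concatenated defined slots; equals the zipper substring of the
        protein."""
        return "".join(h.defined() for h in self.heptads)


@dataclass(frozen=True)
class GEPairCall:
    heptad_index: int
    g_res: str | None
    e_res: str | None
    category: str


@dataclass(frozen=True)
class DimerCall:
    protein_id: str
    category: str
    n_attractive: int
    n_repulsive: int
    n_asn_a: int


def assign_heptads(domain: BZipDomain, seq: str) -> ZipperRegister:
    """Partition the zipper of a located domain into heptads.

    L0 starts four residues before the anchor leucine; subsequent heptads
    are consecutive 7-residue windows, stopping at ``domain.zipper_end``
    (the sequence end or the end of L9).  A trailing partial heptad is
    retained with absent slots; a truncated L0 has absent leading slots.
    """
    domain.validate(seq)
    return register_from_anchor(
        domain.protein_id, seq, domain.anchor_leu, domain.zipper_end
    )


def register_from_anchor(
    protein_id: str, seq: str, anchor: int, zipper_end: int | None = None
) -> ZipperRegister:
    """Build a register directly from an anchor-leucine index (used for
    zipper fragments that carry no basic region, where L0 may be
    truncated by the sequence start)."""
    if not 0 <= anchor < len(seq) or seq[anchor] != "L":
        raise ValueError(f"{protein_id}: anchor {anchor} does not hold an L")
    if zipper_end is None:
        zipper_end = min(len(seq), anchor - 4 + 7 * MAX_HEPTADS)
    start = anchor - 4
    heptads = []
    for n in range(MAX_HEPTADS):
        w0 = start + 7 * n
        if w0 >= zipper_end:
            break
        slots = {}
        for j, slot in enumerate(SLOT_ORDER):
            p = w0 + j
            slots[slot] = seq[p] if 0 <= p < zipper_end else None
        heptads.append(Heptad(index=n, slots=slots))
    return ZipperRegister(
        protein_id=protein_id,
        heptads=tuple(heptads),
        truncated_l0=start < 0,
    )


def classify_a_residue(res: str | None) -> str | None:
    """Class of an a-slot residue: asn / hydrophobic (I,V,L,M) /
    charged (R,K,E,D) / other; None for an absent slot."""
    if res is None:
        return None
    if res == "N":
        return "asn"
    if res in A_HYDROPHOBIC:
        return "hydrophobic"
    if res in CHARGED_RESIDUES:
        return "charged"
    return "other"


def classify_d_residue(res: str | None) -> str | None:
    """Class of a d-slot residue: leucine / other_hydrophobic (I,V,M) /
    other; None for an absent slot."""
    if res is None:
        return None
    if res == "L":
        return "leucine"
    if res in D_OTHER_HYDROPHOBIC:
        return "other_hydrophobic"
    return "other"


def call_ge_pair(heptad: Heptad) -> GEPairCall:
    """Type the g<->e' pair of one heptad.

    The register starts at g, so the e slot of the same heptad is the
    partner-helix position five residues downstream of g; a pair is
    complete only when both residues are charged (R, K, E, D).
    """
    g, e = heptad.slots["g"], heptad.slots["e"]
    if g is None or e is None or g not in CHARGED_RESIDUES or e not in CHARGED_RESIDUES:
        category = "incomplete"
    elif g in BASIC_RESIDUES and e in ACIDIC_RESIDUES:
        category = "attractive_basic_acidic"
    elif g in ACIDIC_RESIDUES and e in BASIC_RESIDUES:
        category = "attractive_acidic_basic"
    elif g in BASIC_RESIDUES:
        category = "repulsive_basic"
    else:
        category = "repulsive_acidic"
    return GEPairCall(heptad_index=heptad.index, g_res=g, e_res=e, category=category)


def classify_dimerization(register: ZipperRegister) -> DimerCall:
    """Bin a protein into the three dimerization categories.

    With A attractive pairs, Rp repulsive pairs and N a-position
    asparagines: I iff A>=1, Rp=0, N>=1; III iff Rp>=1, A=0; II iff both
    pair kinds occur, or attractive pairs occur without Asn;
    indeterminate iff no complete pair at all.
    """
    pairs = [call_ge_pair(h) for h in register.heptads]
    n_attr = sum(p.category.startswith("attractive") for p in pairs)
    n_rep = sum(p.category.startswith("repulsive") for p in pairs)
    n_asn = sum(h.slots["a"] == "N" for h in register.heptads)
    if n_attr == 0 and n_rep == 0:
        category = "indeterminate"
    elif n_rep >= 1 and n_attr == 0:
        category = "III_heterodimer"
    elif n_attr >= 1 and n_rep == 0 and n_asn >= 1:
        category = "I_homodimer"
    else:
        category = "II_both"
    return DimerCall(
        protein_id=register.protein_id,
        category=category,
        n_attractive=n_attr,
        n_repulsive=n_rep,
        n_asn_a=n_asn,
    )
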