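"""Synthetic inputs with planted, recoverable structure.

Every generator is a pure function of (design, seed) and returns the
planted truth beside the data, so any downstream stage can be scored
without re-deriving intent:

* designed bZIP proteins — a basic region matching N-X7-[RK]-X9 followed
  by a leucine zipper realizing a per-heptad design (a-slot residues,
  d-slot residues, g<->e' pair categories);
* decoy proteins guaranteed to violate the basic-region grammar;
* promoters with planted A/G/C-box occurrences in consensus-free
  background;
* expression panels with planted pairwise correlation.

Non-signal positions are drawn from {A,S,T,Q,G} — an alphabet excluding
N, I, V, L, M, R, K, E, D — so planted category counts are exact and
recovery tests are deterministic.  The expected-truth planners in this
module recompute category calls and summary tables directly from the
design, independently of the profiling code they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DnaRecord, ExpressionTable, ProteinRecord

NON_SIGNAL = "ASTQG"
MAX_ATTEMPTS = 10_000

#: Residue realization for each requested g<->e' pair category.
GE_REALIZATION = {
    "attractive_basic_acidic": ("K", "E"),
    "attractive_acidic_basic": ("E", "K"),
    "repulsive_basic": ("K", "R"),
    "repulsive_acidic": ("D", "E"),
    "incomplete": ("K", "A"),
}

BOX_WORDS = {
    "A-box": "TACGTA",
    "G-box": "CACGTG",
    "C-box": "GACGTC",
    "ACGT-core": "ACGT",
}
_HEXAMER_BOXES = ("A-box", "G-box", "C-box")


class UnrealizableDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# protein generation


@dataclass
class ZipperDesign:
    """Per-heptad plan for a synthetic leucine zipper.

    ``a_slots`` / ``d_slots`` map heptad index -> residue (defaults:
    random non-signal at a, leucine at d); ``ge_design`` maps heptad
    index -> pair category (default incomplete).  ``truncate_l0`` builds
    a zipper-only record whose g slot of L0 falls before the sequence
    start (such records have no basic region, which is what makes the
    truncation possible).
    """

    n_heptads: int
    a_slots: dict[int, str] = field(default_factory=dict)
    d_slots: dict[int, str] = field(default_factory=dict)
    ge_design: dict[int, str] = field(default_factory=dict)
    truncate_l0: bool = False

    def validate(self) -> None:
        if not 2 <= self.n_heptads <= 10:
            raise UnrealizableDesignError("n_heptads must be between 2 and 10")
        for mapping in (self.a_slots, self.d_slots, self.ge_design):
            for h in mapping:
                if not 0 <= h < self.n_heptads:
                    raise UnrealizableDesignError(f"heptad index {h} outside design")
        if self.a_slots.get(0) == "L":
            raise UnrealizableDesignError(
                "Leu at the a slot of L0 would sit before the anchor and mis-anchor the register"
            )
        if self.d_slots.get(0, "L") != "L":
            raise UnrealizableDesignError("slot d of L0 must be the anchor leucine")
        if "N" in self.d_slots.values():
            raise UnrealizableDesignError(
                "Asn at a d slot can seed a spurious basic-region match"
            )
        for h, cat in self.ge_design.items():
            if cat not in GE_REALIZATION:
                raise UnrealizableDesignError(f"unknown g-e pair category {cat!r}")

    # --- planners: expected truth derived from the design alone ---

    def planned_pair_categories(self) -> list[str]:
        return [self.ge_design.get(h, "incomplete") for h in range(self.n_heptads)]

    def planned_dimer_category(self) -> str:
        cats = self.planned_pair_categories()
        n_attr = sum(c in ("attractive_basic_acidic", "attractive_acidic_basic") for c in cats)
        n_rep = sum(c in ("repulsive_basic", "repulsive_acidic") for c in cats)
        n_asn = sum(res == "N" for res in self.a_slots.values())
        if n_attr == 0 and n_rep == 0:
            return "indeterminate"
        if n_rep >= 1 and n_attr == 0:
            return "III_heterodimer"
        if n_attr >= 1 and n_rep == 0 and n_asn >= 1:
            return "I_homodimer"
        return "II_both"


def _rand_residues(rng: np.random.Generator, alphabet: str, k: int) -> str:
    return "".join(rng.choice(list(alphabet), size=k))


def _realize_zipper(design: ZipperDesign, rng: np.random.Generator) -> tuple[str, list[str], list[str]]:
    """Build the zipper string (slot order g,a,b,c,d,e,f per heptad) and
    return it with the realized a- and d-slot residues."""
    parts, a_res, d_res = [], [], []
    for h in range(design.n_heptads):
        g, e = GE_REALIZATION[design.ge_design.get(h, "incomplete")]
        a = design.a_slots.get(h) or _rand_residues(rng, NON_SIGNAL, 1)
        d = design.d_slots.get(h, "L")
        b, c, f = (_rand_residues(rng, NON_SIGNAL, 1) for _ in range(3))
        parts.append(g + a + b + c + d + e + f)
        a_res.append(a)
        d_res.append(d)
    return "".join(parts), a_res, d_res


def make_bzip_protein(
    design: ZipperDesign,
    seed: int,
    protein_id: str = "synthetic_bzip",
    n_pad_range: tuple[int, int] = (5, 30),
    c_pad: int = 0,
) -> tuple[ProteinRecord, dict]:
    """A synthetic bZIP protein realizing ``design``, with planted truth.

    Layout: non-signal N-terminal pad, 18-residue basic region
    (N-X7-[RK]-X9 with X non-signal), zipper, optional non-signal
    C-terminal pad (default empty, so the register length equals the
    designed heptad count).  Deterministic under ``seed``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    zipper, a_res, d_res = _realize_zipper(design, rng)
    if design.truncate_l0:
        # zipper-only record starting at the a slot of L0 (3 residues
        # before the anchor); no basic region, hence the truncation.
        seq = zipper[1:]
        anchor = 3
        basic_start = basic_end = None
    else:
        n_pad = int(rng.integers(n_pad_range[0], n_pad_range[1] + 1))
        pad = _rand_residues(rng, NON_SIGNAL, n_pad)
        basic = (
            "N"
            + _rand_residues(rng, NON_SIGNAL, 7)
            + str(rng.choice(["R", "K"]))
            + _rand_residues(rng, NON_SIGNAL, 9)
        )
        seq = pad + basic + zipper + _rand_residues(rng, NON_SIGNAL, c_pad)
        basic_start, basic_end = n_pad, n_pad + 18
        anchor = basic_end + 4
    truth = {
        "protein_id": protein_id,
        "basic_start": basic_start,
        "basic_end": basic_end,
        "anchor": anchor,
        "n_heptads": design.n_heptads,
        "a_residues": a_res,
        "d_residues": d_res,
        "pair_categories": design.planned_pair_categories(),
        "dimer_category": design.planned_dimer_category(),
        "truncated_l0": design.truncate_l0,
    }
    return ProteinRecord(id=protein_id, sequence=seq), truth


def make_decoy_protein(length: int, seed: int, protein_id: str = "decoy") -> ProteinRecord:
    """A random protein containing no N-X7-[RK]-X9 window (rejection
    sampling, bounded attempts)."""
    import re

    if length < 20:
        raise ValueError("decoy length must be at least 20")
    rng = np.random.default_rng(seed)
    pattern = re.compile(r"(?=(N.{7}[RK].{9}))")
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(MAX_ATTEMPTS):
        seq = "".join(rng.choice(alphabet, size=length))
        if not pattern.search(seq):
            return ProteinRecord(id=protein_id, sequence=seq)
    raise RuntimeError("could not generate a grammar-free decoy within the attempt bound")


def random_zipper_design(rng: np.random.Generator, heptad_range: tuple[int, int] = (2, 9)) -> ZipperDesign:
    """Sample a design with family-survey-like slot frequencies:
    a — ~19% Asn, ~35% hydrophobic, ~20% charged, rest other;
    d — ~50% Leu, ~31% other hydrophobic, rest other;
    g<->e' — attractive-leaning mixture with incomplete pairs common."""
    n = int(rng.integers(heptad_range[0], heptad_range[1] + 1))
    a_slots, d_slots, ge = {}, {}, {}
    for h in range(n):
        u = rng.random()
        if u < 0.19:
            a_slots[h] = "N"
        elif u < 0.54:
            pool = "IVM" if h == 0 else "IVLM"
            a_slots[h] = str(rng.choice(list(pool)))
        elif u < 0.74:
            a_slots[h] = str(rng.choice(list("RKED")))
        # else: leave random non-signal ("other")
        v = rng.random()
        if h == 0 or v < 0.50:
            d_slots[h] = "L"
        elif v < 0.81:
            d_slots[h] = str(rng.choice(list("IVM")))
        # else: leave default... default is L, so set explicitly
        else:
            d_slots[h] = str(rng.choice(list(NON_SIGNAL)))
        ge[h] = str(
            rng.choice(
                list(GE_REALIZATION),
                p=[0.30, 0.15, 0.07, 0.08, 0.40],
            )
        )
    return ZipperDesign(n_heptads=n, a_slots=a_slots, d_slots=d_slots, ge_design=ge)


@dataclass
class FamilyDesign:
    """A designed protein family with records, per-protein truth, and
    expected family-level tables planned from the designs alone."""

    designs: list[ZipperDesign]
    records: list[ProteinRecord]
    truths: list[dict]

    def expected_position_composition(self, position: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for truth in self.truths:
            residues = truth["a_residues"] if position == "a" else truth["d_residues"]
            for res in residues:
                if position == "a":
                    cls = (
                        "asn" if res == "N"
                        else "hydrophobic" if res in "IVLM"
                        else "charged" if res in "RKED"
                        else "other"
                    )
                else:
                    cls = (
                        "leucine" if res == "L"
                        else "other_hydrophobic" if res in "IVM"
                        else "other"
                    )
                counts[cls] = counts.get(cls, 0) + 1
        return counts

    def expected_asn_histogram(self) -> dict[int, int]:
        counts = {n: 0 for n in range(10)}
        for truth in self.truths:
            for h, res in enumerate(truth["a_residues"]):
                if res == "N":
                    counts[h] += 1
        return counts

    def expected_ge_histogram(self) -> dict[int, dict[str, int]]:
        counts: dict[int, dict[str, int]] = {n: {} for n in range(10)}
        for truth in self.truths:
            for h, cat in enumerate(truth["pair_categories"]):
                counts[h][cat] = counts[h].get(cat, 0) + 1
        return counts

    def expected_dimer_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for truth in self.truths:
            counts[truth["dimer_category"]] = counts.get(truth["dimer_category"], 0) + 1
        return counts


def make_family(
    n_proteins: int,
    seed: int,
    heptad_range: tuple[int, int] = (2, 9),
    id_prefix: str = "synZIP",
) -> FamilyDesign:
    """A family of randomly designed bZIP proteins (deterministic under
    seed)."""
    rng = np.random.default_rng(seed)
    designs, records, truths = [], [], []
    for i in range(n_proteins):
        design = random_zipper_design(rng, heptad_range)
        rec, truth = make_bzip_protein(
            design, seed=int(rng.integers(0, 2**31 - 1)), protein_id=f"{id_prefix}{i + 1}"
        )
        designs.append(design)
        records.append(rec)
        truths.append(truth)
    return FamilyDesign(designs=designs, records=records, truths=truths)


# ---------------------------------------------------------------------------
# promoter generation


@dataclass
class PromoterDesign:
    """Planted (box, offset) occurrences inside a window whose 3' end is
    the translation start; offsets are negative 1-based upstream
    coordinates of the 5'-most base."""

    promoter_id: str
    planted: list[tuple[str, int]] = field(default_factory=list)
    length: int = 1500

    def validate(self) -> None:
        spans = []
        for box, offset in self.planted:
            if box not in BOX_WORDS:
                raise UnrealizableDesignError(f"unknown box {box!r}")
            w = len(BOX_WORDS[box])
            if not -self.length <= offset <= -w:
                raise UnrealizableDesignError(
                    f"{box} at {offset} does not fit inside the {self.length}-nt window"
                )
            start = self.length + offset
            spans.append((start, start + w))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise UnrealizableDesignError("planted boxes overlap")


def make_promoter(design: PromoterDesign, seed: int) -> tuple[DnaRecord, list[tuple[str, int]]]:
    """A promoter with exactly the planted box occurrences.

    The background is rejection-resampled until none of the three named
    hexamer consensi occurs anywhere except at a planted position (the
    consensi are palindromic, so a plus-strand check covers both
    strands).  Deterministic under seed; bounded attempts.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    planted_positions = {
        (box, design.length + offset) for box, offset in design.planted
    }
    bases = np.array(list("ACGT"))
    for _ in range(MAX_ATTEMPTS):
        seq = rng.choice(bases, size=design.length)
        for box, offset in design.planted:
            start = design.length + offset
            word = BOX_WORDS[box]
            seq[start : start + len(word)] = list(word)
        s = "".join(seq)
        found = set()
        for box in _HEXAMER_BOXES:
            word = BOX_WORDS[box]
            start = 0
            while True:
                i = s.find(word, start)
                if i < 0:
                    break
                found.add((box, i))
                start = i + 1
        if found == {(b, p) for b, p in planted_positions if b in _HEXAMER_BOXES}:
            truth = sorted(((box, off) for box, off in design.planted), key=lambda t: t[1])
            return DnaRecord(id=design.promoter_id, sequence=s), truth
    raise RuntimeError("could not generate a consensus-free background within the attempt bound")


# ---------------------------------------------------------------------------
# expression generation


@dataclass
class ExpressionDesign:
    """Two gene panels measured over shared samples, with planted
    pairwise Pearson correlations (rho per (tf, target) pair; unplanted
    pairs independent).  ``baseline`` shifts values away from zero so the
    tables read as relative expression; the shift does not affect r."""

    tf_genes: list[str]
    lpg_genes: list[str]
    n_samples: int
    planted: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline: float = 5.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise UnrealizableDesignError("need at least 2 samples")
        if set(self.tf_genes) & set(self.lpg_genes):
            raise UnrealizableDesignError("TF and target panels must be disjoint")
        for (a, b), rho in self.planted.items():
            if a not in self.tf_genes or b not in self.lpg_genes:
                raise UnrealizableDesignError(f"planted pair ({a}, {b}) outside the panels")
            if not -1.0 <= rho <= 1.0:
                raise UnrealizableDesignError(f"rho {rho} outside [-1, 1]")


def _components(genes: list[str], edges: Mapping[tuple[str, str], float]):
    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for g in genes:
        comps.setdefault(find(g), []).append(g)
    return list(comps.values())


def make_expression(
    design: ExpressionDesign, seed: int
) -> tuple[ExpressionTable, ExpressionTable, dict[tuple[str, str], float]]:
    """Draw the two panels from a multivariate normal whose covariance is
    the identity plus the planted correlations; the planted map is
    returned as truth.  A non-positive-semidefinite plant is rejected."""
    design.validate()
    rng = np.random.default_rng(seed)
    genes = list(design.tf_genes) + list(design.lpg_genes)
    order = {g: i for i, g in enumerate(genes)}
    n = design.n_samples
    data = np.empty((len(genes), n))

    comps = _components(genes, design.planted)
    singles = [c[0] for c in comps if len(c) == 1]
    pair_comps = [c for c in comps if len(c) == 2]
    big_comps = [c for c in comps if len(c) > 2]

    # fast paths: independent genes and simple correlated pairs
    if singles:
        idx = [order[g] for g in singles]
        data[idx, :] = rng.standard_normal((len(singles), n))
    if pair_comps:
        rho = np.empty(len(pair_comps))
        idx_a, idx_b = [], []
        for k, comp in enumerate(pair_comps):
            (a, b) = comp
            key = (a, b) if (a, b) in design.planted else (b, a)
            rho[k] = design.planted[key]
            idx_a.append(order[key[0]])
            idx_b.append(order[key[1]])
        x = rng.standard_normal((len(pair_comps), n))
        e = rng.standard_normal((len(pair_comps), n))
        y = rho[:, None] * x + np.sqrt(1.0 - rho**2)[:, None] * e
        data[idx_a, :] = x
        data[idx_b, :] = y
    for comp in big_comps:
        cov = np.eye(len(comp))
        pos = {g: i for i, g in enumerate(comp)}
        for (a, b), rho in design.planted.items():
            if a in pos and b in pos:
                cov[pos[a], pos[b]] = cov[pos[b], pos[a]] = rho
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-9:
            raise UnrealizableDesignError("planted covariance is not positive semidefinite")
        draw = rng.multivariate_normal(np.zeros(len(comp)), cov, size=n, method="svd").T
        for g in comp:
            data[order[g], :] = draw[pos[g], :]

    data = data + design.baseline
    samples = [f"s{i + 1}" for i in range(n)]
    frame = pd.DataFrame(data, index=genes, columns=samples)
    tf = ExpressionTable(values=frame.loc[design.tf_genes].copy(), kind="relative")
    lpg = ExpressionTable(values=frame.loc[design.lpg_genes].copy(), kind="relative")
    return tf, lpg, dict(design.planted)
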