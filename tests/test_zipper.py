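import numpy as np
import pytest

from zipprofiler.domains import scan_protein
from zipprofiler.simulate import ZipperDesign, make_bzip_protein
from zipprofiler.zipper import (
    SLOT_ORDER,
    Heptad,
    ZipperRegister,
    assign_heptads,
    call_ge_pair,
    classify_a_residue,
    classify_d_residue,
    classify_dimerization,
    register_from_anchor,
)


def heptad(index=0, **slots):
    full = {s: None for s in SLOT_ORDER}
    full.update(slots)
    return Heptad(index=index, slots=full)


def register(*heptads, protein_id="p", truncated=False):
    return ZipperRegister(protein_id=protein_id, heptads=tuple(heptads),
                          truncated_l0=truncated)


def oracle_slots(seq, anchor, zipper_end):
    """Index-arithmetic oracle: slot(p) = 'gabcdef'[(p - (anchor-4)) % 7]."""
    out = {}
    for p in range(max(anchor - 4, 0), zipper_end):
        rel = p - (anchor - 4)
        out[(rel // 7, SLOT_ORDER[rel % 7])] = seq[p]
    return out


class TestAssignHeptads:
    def test_l0_covers_four_before_anchor_plus_two_after(self):
        seq = "MKRKNAEQLAKELAELKNEASK"
        reg = register_from_anchor("p", seq, anchor=8)
        l0 = reg.heptads[0].slots
        assert [l0[s] for s in SLOT_ORDER] == list("NAEQLAK")

    def test_register_capped_at_ten_heptads(self):
        # a 12-heptad-long periodic zipper: assignment must stop at L9
        seq = "GGGG" + ("LAAAAAA" * 12)
        reg = register_from_anchor("p", seq, anchor=4)
        assert reg.n_heptads == 10
        assert reg.heptads[-1].index == 9

    def test_slots_match_index_arithmetic_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            design = ZipperDesign(n_heptads=n)
            rec, truth = make_bzip_protein(design, seed=int(rng.integers(2**31)))
            dom = scan_protein(rec)
            reg = assign_heptads(dom, rec.sequence)
            expected = oracle_slots(rec.sequence, dom.anchor_leu, dom.zipper_end)
            got = {
                (h.index, s): h.slots[s]
                for h in reg.heptads
                for s in SLOT_ORDER
                if h.slots[s] is not None
            }
            assert got == expected

    def test_reconstruction_is_identity(self, four_heptad_protein):
        _, rec, _ = four_heptad_protein
        dom = scan_protein(rec)
        reg = assign_heptads(dom, rec.sequence)
        assert reg.sequence() == rec.sequence[dom.anchor_leu - 4 : dom.zipper_end]

    def test_truncated_l0_has_absent_leading_slots(self):
        # anchor at index 3: only a,b,c precede it; g of L0 is absent
        seq = "ABC" + "LEG" + "KAAALEG"
        seq = seq.replace("B", "S")  # keep to the protein alphabet
        reg = register_from_anchor("p", seq, anchor=3)
        assert reg.truncated_l0
        l0 = reg.heptads[0].slots
        assert l0["g"] is None and l0["d"] == "L"

    def test_trailing_partial_heptad_retained_with_absent_slots(self):
        seq = "GGGG" + "LAAAAAA" + "LA"  # 13 residues: L1 stops at slot e
        reg = register_from_anchor("p", seq, anchor=4)
        assert reg.n_heptads == 2
        l1 = reg.heptads[1].slots
        assert l1["d"] == "L" and l1["f"] is None


class TestResidueClassifiers:
    @pytest.mark.parametrize(
        "res,expected",
        [("N", "asn"), ("V", "hydrophobic"), ("I", "hydrophobic"), ("L", "hydrophobic"),
         ("M", "hydrophobic"), ("R", "charged"), ("K", "charged"), ("E", "charged"),
         ("D", "charged"), ("S", "other"), ("H", "other"), (None, None)],
    )
    def test_a_position_classes(self, res, expected):
        assert classify_a_residue(res) == expected

    @pytest.mark.parametrize(
        "res,expected",
        [("L", "leucine"), ("I", "other_hydrophobic"), ("V", "other_hydrophobic"),
         ("M", "other_hydrophobic"), ("E", "other"), ("F", "other"), (None, None)],
    )
    def test_d_position_classes(self, res, expected):
        assert classify_d_residue(res) == expected


class TestGEPairCalls:
    @pytest.mark.parametrize(
        "g,e,expected",
        [("K", "E", "attractive_basic_acidic"), ("R", "D", "attractive_basic_acidic"),
         ("E", "K", "attractive_acidic_basic"), ("D", "R", "attractive_acidic_basic"),
         ("K", "R", "repulsive_basic"), ("D", "E", "repulsive_acidic"),
         ("K", "A", "incomplete"), ("A", "E", "incomplete"),
         ("H", "E", "incomplete"),  # His is not counted as charged
         (None, "E", "incomplete")],
    )
    def test_pair_categories(self, g, e, expected):
        call = call_ge_pair(heptad(g=g, e=e, d="L"))
        assert call.category == expected

    def test_complete_iff_both_charged(self, rng):
        charged = set("RKED")
        for _ in range(100):
            g, e = (str(x) for x in rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2))
            call = call_ge_pair(heptad(g=g, e=e, d="L"))
            assert (call.category != "incomplete") == (g in charged and e in charged)


class TestDimerClassification:
    def test_attractive_pairs_plus_asn_is_homodimer(self):
        reg = register(
            heptad(0, g="K", e="E", d="L", a="A"),
            heptad(1, g="E", e="K", d="L", a="A"),
            heptad(2, g="A", e="A", d="L", a="N"),
        )
        assert classify_dimerization(reg).category == "I_homodimer"

    def test_repulsive_only_is_heterodimer(self):
        reg = register(
            heptad(0, g="K", e="R", d="L", a="A"),
            heptad(1, g="K", e="K", d="L", a="A"),
            heptad(2, g="D", e="E", d="L", a="A"),
        )
        call = classify_dimerization(reg)
        assert call.category == "III_heterodimer"
        assert call.n_repulsive == 3 and call.n_attractive == 0

    def test_mixed_pairs_are_both(self):
        reg = register(
            heptad(0, g="K", e="E", d="L", a="N"),
            heptad(1, g="K", e="K", d="L", a="A"),
        )
        assert classify_dimerization(reg).category == "II_both"

    def test_attractive_without_asn_falls_to_both(self):
        reg = register(heptad(0, g="K", e="E", d="L", a="A"))
        assert classify_dimerization(reg).category == "II_both"

    def test_no_complete_pair_no_asn_is_indeterminate(self):
        reg = register(heptad(0, g="A", e="A", d="L", a="A"))
        assert classify_dimerization(reg).category == "indeterminate"

    def test_categories_partition_random_registers(self, small_family):
        from zipprofiler.domains import scan_protein

        cats = []
        for rec in small_family.records:
            reg = assign_heptads(scan_protein(rec), rec.sequence)
            cats.append(classify_dimerization(reg).category)
        assert all(
            c in ("I_homodimer", "II_both", "III_heterodimer", "indeterminate")
            for c in cats
        )
        assert len(cats) == len(small_family.records)
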