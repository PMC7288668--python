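import math

import numpy as np
import pandas as pd
import pytest

from zipprofiler.expression import (
    correlate,
    delta_delta_ct,
    edges_to_frame,
    pair_correlation,
    scale_rows,
)
from zipprofiler.records import ExpressionTable


def ct_table(data, samples):
    return ExpressionTable(
        values=pd.DataFrame.from_dict(data, orient="index", columns=samples),
        kind="ct",
    )


def rel_table(data, samples):
    return ExpressionTable(
        values=pd.DataFrame.from_dict(data, orient="index", columns=samples),
        kind="relative",
    )


class TestDeltaDeltaCt:
    def test_two_cycle_advantage_is_sixteen_fold(self):
        ct = ct_table({"ref": [18.0, 18.0], "tgt": [24.0, 20.0]}, ["cal", "s"])
        out = delta_delta_ct(ct, "ref", "cal")
        row = out[(out["gene"] == "tgt") & (out["sample"] == "s")].iloc[0]
        assert row["ddct"] == pytest.approx(-4.0)
        assert row["fold_change"] == pytest.approx(16.0)

    def test_calibrator_fold_is_one(self):
        ct = ct_table({"ref": [18.0, 19.0], "tgt": [24.0, 22.0]}, ["cal", "s"])
        out = delta_delta_ct(ct, "ref", "cal")
        cal = out[out["sample"] == "cal"]
        assert np.allclose(cal["fold_change"], 1.0)

    def test_fold_multiplicativity_across_calibrators(self, rng):
        samples = ["a", "b", "c"]
        for _ in range(10):
            ct = ct_table(
                {
                    "ref": list(15 + 10 * rng.random(3)),
                    "tgt": list(15 + 10 * rng.random(3)),
                },
                samples,
            )
            folds = {
                cal: delta_delta_ct(ct, "ref", cal).set_index("sample")["fold_change"]
                for cal in samples
            }
            assert folds["b"]["a"] * folds["c"]["b"] == pytest.approx(folds["c"]["a"])

    def test_missing_reference_sample_excluded_with_warning(self, caplog):
        ct = ct_table(
            {"ref": [18.0, float("nan")], "tgt": [24.0, 20.0]}, ["cal", "s"]
        )
        with caplog.at_level("WARNING"):
            out = delta_delta_ct(ct, "ref", "cal")
        assert set(out["sample"]) == {"cal"}
        assert "excluded" in caplog.text

    def test_absent_reference_gene_is_an_error(self):
        ct = ct_table({"tgt": [24.0, 20.0]}, ["cal", "s"])
        with pytest.raises(KeyError):
            delta_delta_ct(ct, "ref", "cal")

    def test_missing_target_ct_yields_missing_fold(self):
        ct = ct_table(
            {"ref": [18.0, 18.0], "tgt": [24.0, float("nan")]}, ["cal", "s"]
        )
        out = delta_delta_ct(ct, "ref", "cal")
        row = out[(out["gene"] == "tgt") & (out["sample"] == "s")].iloc[0]
        assert math.isnan(row["fold_change"])


class TestScaleRows:
    def test_closed_form_row(self):
        t = rel_table({"g": [1.0, 2.0, 3.0]}, ["a", "b", "c"])
        out = scale_rows(t)
        assert np.allclose(out.values.loc["g"], [-1.0, 0.0, 1.0])
        assert out.kind == "normalized"

    def test_output_rows_standardized(self, rng):
        t = rel_table({f"g{i}": list(rng.random(6)) for i in range(5)}, list("abcdef"))
        out = scale_rows(t)
        for _, row in out.values.iterrows():
            assert row.mean() == pytest.approx(0.0, abs=1e-12)
            assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_becomes_missing_with_warning(self, caplog):
        t = rel_table({"g": [5.0, 5.0, 5.0]}, ["a", "b", "c"])
        with caplog.at_level("WARNING"):
            out = scale_rows(t)
        assert out.values.loc["g"].isna().all()
        assert "variance" in caplog.text

    def test_missing_values_propagate(self):
        t = rel_table({"g": [1.0, float("nan"), 3.0, 5.0]}, list("abcd"))
        out = scale_rows(t)
        assert math.isnan(out.values.loc["g", "b"])
        assert out.values.loc["g"].dropna().mean() == pytest.approx(0.0, abs=1e-12)


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        tf = rel_table({"t": x}, list("abcde"))
        lpg = rel_table({"g": [2 * v for v in x]}, list("abcde"))
        edge = correlate(tf, lpg)[0]
        assert edge.r == pytest.approx(1.0)
        assert edge.sign == "positive" and edge.significant

    def test_hand_computed_pearson(self):
        tf = rel_table({"t": [1.0, 2.0, 3.0, 4.0]}, list("abcd"))
        lpg = rel_table({"g": [2.0, 1.0, 4.0, 3.0]}, list("abcd"))
        assert correlate(tf, lpg)[0].r == pytest.approx(0.6)

    def test_edge_count_is_cartesian_product(self, rng):
        tf = rel_table({f"t{i}": list(rng.random(5)) for i in range(3)}, list("abcde"))
        lpg = rel_table({f"g{i}": list(rng.random(5)) for i in range(4)}, list("abcde"))
        edges = correlate(tf, lpg)
        assert len(edges) == 12
        assert sum(e.significant for e in edges) <= 12

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.random(8), rng.random(8)
        samples = list("abcdefgh")
        r1 = correlate(rel_table({"t": x}, samples), rel_table({"g": y}, samples))[0].r
        r2 = correlate(rel_table({"t": y}, samples), rel_table({"g": x}, samples))[0].r
        r3 = correlate(
            rel_table({"t": 3.0 * x + 2.0}, samples), rel_table({"g": y}, samples)
        )[0].r
        assert r1 == pytest.approx(r2) and r1 == pytest.approx(r3)

    def test_too_few_pairs_yield_missing_r(self):
        tf = rel_table({"t": [1.0, 2.0, float("nan")]}, list("abc"))
        lpg = rel_table({"g": [2.0, 1.0, 4.0]}, list("abc"))
        edge = correlate(tf, lpg)[0]
        assert math.isnan(edge.r) and not edge.significant

    def test_mismatched_sample_sets_rejected(self):
        tf = rel_table({"t": [1.0, 2.0]}, ["a", "b"])
        lpg = rel_table({"g": [1.0, 2.0]}, ["a", "c"])
        with pytest.raises(ValueError):
            correlate(tf, lpg)

    def test_spearman_matches_rank_transform(self, rng):
        x, y = rng.random(10), rng.random(10)
        samples = [f"s{i}" for i in range(10)]
        rho = correlate(
            rel_table({"t": x}, samples), rel_table({"g": y}, samples),
            method="spearman",
        )[0].r
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        _, r_ranks, _ = pair_correlation(rx, ry, method="pearson")
        assert rho == pytest.approx(r_ranks)

    def test_bh_adjustment_never_creates_significance(self, rng):
        samples = list("abcdefgh")
        tf = rel_table({f"t{i}": list(rng.random(8)) for i in range(4)}, samples)
        lpg = rel_table({f"g{i}": list(rng.random(8)) for i in range(4)}, samples)
        raw = {(e.gene_a, e.gene_b): e.significant for e in correlate(tf, lpg)}
        adjusted = correlate(tf, lpg, adjust="bh")
        for e in adjusted:
            assert not e.significant or raw[(e.gene_a, e.gene_b)]

    def test_edges_frame_columns(self, rng):
        tf = rel_table({"t": list(rng.random(5))}, list("abcde"))
        lpg = rel_table({"g": list(rng.random(5))}, list("abcde"))
        frame = edges_to_frame(correlate(tf, lpg))
        assert list(frame.columns) == ["gene_a", "gene_b", "n", "r", "p", "sign", "significant"]
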