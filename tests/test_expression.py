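"""FPKM, Fisher's exact test, CV and the classification summary."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from helpers_oracles import fisher_two_sided_oracle
from methexpr import (
    CountMatrix,
    GeneModel,
    SampleSheet,
    Thresholds,
    coefficient_of_variation,
    compute_fpkm,
    differential_expression,
    expression_summary,
    fisher_exact_two_sided,
)


def _gene(gid, length=1000, chrom="chr1", strand="+", tss=50_000):
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss, gene_length=length)


def _sheet(n=3):
    ctl = [f"c{i}" for i in range(n)]
    tol = [f"t{i}" for i in range(n)]
    return SampleSheet(
        samples=tuple(ctl + tol),
        groups={**{s: "control" for s in ctl}, **{s: "tolerized" for s in tol}},
    )


class TestFpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 1000, 1_000_000, 100.0), (0, 1000, 1_000_000, 0.0), (50, 2000, 5_000_000, 5.0)],
    )
    def test_formula(self, count, length, lib, expected):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [count]}, index=["g1"]),
            library_size=pd.Series([lib], index=["s1"]),
        )
        fpkm = compute_fpkm(cm, [_gene("g1", length=length)])
        assert fpkm.loc["g1", "s1"] == pytest.approx(expected)

    def test_missing_gene_length_named(self):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [1]}, index=["gX"]),
            library_size=pd.Series([100], index=["s1"]),
        )
        with pytest.raises(ValueError, match="gX"):
            compute_fpkm(cm, [_gene("g1")])

    def test_zero_library_size_rejected(self):
        cm = CountMatrix(
            counts=pd.DataFrame({"s1": [1]}, index=["g1"]),
            library_size=pd.Series([0], index=["s1"]),
        )
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(cm, [_gene("g1")])


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        # margins (10,10,10,10): only the two extreme tables are as improbable
        assert fisher_exact_two_sided([[0, 10], [10, 0]]) == pytest.approx(
            2 / 184756, rel=1e-9
        )

    @pytest.mark.parametrize(
        "table",
        [
            [[2, 8], [8, 2]],
            [[1, 9], [4, 6]],
            [[12, 3], [5, 17]],
            [[0, 0], [3, 5]],
            [[7, 0], [0, 9]],
        ],
    )
    def test_matches_oracle_and_scipy(self, table):
        (a, b), (c, d) = table
        p = fisher_exact_two_sided(table)
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)
        assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-7)

    def test_large_counts_match_scipy(self):
        table = [[140_000, 610_000], [104_000, 646_000]]
        assert fisher_exact_two_sided(table) == pytest.approx(
            scipy_fisher(table)[1], rel=1e-6, abs=1e-300
        )

    def test_all_zero_table_flagged(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_two_sided([[0, 0], [0, 0]])

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12), c=st.integers(0, 12), d=st.integers(0, 12)
    )
    @settings(derandomize=True, max_examples=60)
    def test_row_swap_invariance_and_range(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p1 = fisher_exact_two_sided([[a, b], [c, d]])
        p2 = fisher_exact_two_sided([[c, d], [a, b]])
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert 0 < p1 <= 1


class TestCv:
    @given(x=st.floats(min_value=1e-6, max_value=1e9, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_single_replicate_detection_is_sqrt3(self, x):
        assert coefficient_of_variation([x, 0.0, 0.0]) == pytest.approx(np.sqrt(3))

    def test_identities(self):
        assert coefficient_of_variation([4.2, 4.2, 4.2]) == pytest.approx(0.0)
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert np.isnan(coefficient_of_variation([0.0, 0.0, 0.0]))


class TestDifferentialExpression:
    def _cm(self, rows, sheet):
        counts = pd.DataFrame(rows, columns=list(sheet.samples)).astype("int64")
        counts.index = [f"g{i + 1}" for i in range(len(counts))]
        return CountMatrix.from_counts(counts)

    def test_identical_groups_unchanged(self):
        sheet = _sheet()
        cm = self._cm([[10, 10, 10, 10, 10, 10], [90, 90, 90, 90, 90, 90]], sheet)
        genes = [_gene("g1"), _gene("g2")]
        res = differential_expression(cm, genes, sheet)
        assert res["fc_expr"].tolist() == pytest.approx([1.0, 1.0])
        assert set(res["expr_class"]) == {"unchanged"}

    def test_twofold_boundary_is_up_inclusive(self):
        sheet = _sheet()
        # g1 doubles while g2 holds the library sizes symmetric
        cm = self._cm(
            [[50, 50, 50, 100, 100, 100], [150, 150, 150, 100, 100, 100]], sheet
        )
        genes = [_gene("g1"), _gene("g2")]
        res = differential_expression(cm, genes, sheet)
        assert res.loc["g1", "fc_expr"] == pytest.approx(2.0, rel=1e-6)
        assert res.loc["g1", "expr_class"] == "up"

    def test_undetected_gene_flagged_and_excluded(self):
        sheet = _sheet()
        cm = self._cm([[0, 0, 0, 0, 0, 0], [10, 10, 10, 10, 10, 10]], sheet)
        genes = [_gene("g1"), _gene("g2")]
        res = differential_expression(cm, genes, sheet)
        assert res.loc["g1", "expr_class"] == "undetected"
        assert expression_summary(res)["n_detected"] == 1

    def test_library_scaling_invariance(self):
        sheet = _sheet()
        rows = [[5, 8, 9, 40, 0, 0], [95, 92, 91, 60, 100, 100]]
        cm1 = self._cm(rows, sheet)
        cm2 = CountMatrix(counts=cm1.counts, library_size=cm1.library_size * 17)
        genes = [_gene("g1"), _gene("g2")]
        r1 = differential_expression(cm1, genes, sheet)
        r2 = differential_expression(cm2, genes, sheet)
        assert r1["fc_expr"].to_numpy() == pytest.approx(r2["fc_expr"].to_numpy(), rel=1e-9)
        assert r1["cv"].to_numpy() == pytest.approx(r2["cv"].to_numpy(), nan_ok=True)

    def test_pooled_fisher_table_construction(self):
        sheet = _sheet()
        rows = [[5, 8, 9, 40, 30, 20], [95, 92, 91, 60, 100, 100]]
        cm = self._cm(rows, sheet)
        genes = [_gene("g1"), _gene("g2")]
        res = differential_expression(cm, genes, sheet)
        # gene 1: tolerized 90 of 350, control 22 of 300; "other" = rest of library
        expected = fisher_two_sided_oracle(90, 350 - 90, 22, 300 - 22)
        assert res.loc["g1", "p_expr"] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_flag(self):
        sheet = _sheet()
        rows = [[5, 8, 9, 40, 30, 20], [95, 92, 91, 60, 100, 100]]
        cm = self._cm(rows, sheet)
        res = differential_expression(cm, [_gene("g1"), _gene("g2")], sheet, bh_adjust=True)
        assert "q_expr" in res.columns
        assert (res["q_expr"] >= res["p_expr"]).all()

    def test_null_calibration_near_poisson(self):
        """Pooled-count Fisher keeps roughly nominal size on unspiked,
        near-Poisson replicate counts."""
        from methexpr import SimulationConfig, simulate_counts, generate_genome

        cfg = SimulationConfig(
            seed=5,
            n_genes=40,
            chrom_length=600_000,
            nb_mean=200.0,
            nb_dispersion=5000.0,  # essentially Poisson
            n_up_spiked=0,
            n_down_spiked=0,
            n_candidate_spiked=0,
        )
        genome, genes = generate_genome(cfg)
        cm, _ = simulate_counts(genes, cfg)
        res = differential_expression(cm, genes, cfg.samples)
        frac = (res["p_expr"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res))


class TestSummary:
    def test_percentages_apportioned_to_sum_100(self):
        classes = ["up"] * 3 + ["down"] * 1 + ["unchanged"] * 5 + ["undetected"]
        res = pd.DataFrame({"expr_class": classes})
        s = expression_summary(res)
        assert s["n_detected"] == 9
        assert s["pct_up"] + s["pct_down"] + s["pct_unchanged"] == pytest.approx(100.0)

    def test_zero_up_is_zero_percent(self):
        res = pd.DataFrame({"expr_class": ["unchanged"] * 10})
        assert expression_summary(res)["pct_up"] == 0.0
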