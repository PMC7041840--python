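"""Context classification, promoter windows, window aggregation, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from helpers_oracles import fisher_two_sided_oracle, window_sums_oracle
from methexpr import (
    GeneModel,
    SampleSheet,
    SimulationConfig,
    Thresholds,
    classify_context,
    context_summary,
    genome_cytosines,
    methylation_summary,
    promoter_methylation,
    promoter_window,
    simulate_dataset,
)
from methexpr.io_formats import split_cytosine_reports


def _gene(gid="g1", chrom="chr1", strand="+", tss=15_000, length=1000):
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss, gene_length=length)


def _sheet():
    return SampleSheet(
        samples=("c1", "t1"), groups={"c1": "control", "t1": "tolerized"}
    )


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("TACGA", 2, "+", "CpG"),
            ("TACTG", 2, "+", "CHG"),
            ("TACTT", 2, "+", "CHH"),
            ("ACGT", 2, "-", "CpG"),  # reverse complement reads C then G
            ("AAGTC", 2, "-", "CHH"),
            ("TACGN", 2, "+", "CpG"),  # first downstream base decides CpG alone
            ("TACAN", 2, "+", "undefined"),
            ("TACT", 2, "+", "undefined"),  # second downstream base off-chromosome
        ],
    )
    def test_contexts(self, seq, pos, strand, expected):
        assert classify_context({"chr1": seq}, "chr1", pos, strand) == expected

    def test_non_cytosine_position_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context({"chr1": "AAAA"}, "chr1", 0, "+")

    def test_vectorised_enumeration_matches_scalar(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), size=400, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        genome = {"chr1": seq}
        table = genome_cytosines(genome)
        # every enumerated cytosine agrees with the scalar classifier
        for _, row in table.iterrows():
            assert (
                classify_context(genome, "chr1", int(row["pos"]), row["strand"])
                == row["context"]
            )
        # and no defined-context cytosine was missed
        n_expected = sum(
            1
            for pos in range(400)
            for strand in "+-"
            if (strand == "+" and seq[pos] == "C" or strand == "-" and seq[pos] == "G")
            and classify_context(genome, "chr1", pos, strand) != "undefined"
        )
        assert len(table) == n_expected


class TestPromoterWindow:
    def test_plus_strand(self):
        assert promoter_window(_gene(strand="+", tss=15_000)) == (5_000, 15_000)

    def test_plus_strand_clipped_at_origin(self):
        assert promoter_window(_gene(strand="+", tss=4_000)) == (0, 4_000)

    def test_minus_strand_clipped_at_chrom_end(self):
        g = _gene(strand="-", tss=2_000)
        assert promoter_window(g, chrom_length=30_000) == (2_001, 12_001)
        assert promoter_window(g, chrom_length=5_000) == (2_001, 5_000)

    def test_windows_disjoint_and_exact_in_synthetic_layout(self, small_dataset):
        genes = small_dataset["genes"]
        lengths = {c: len(s) for c, s in small_dataset["genome"].items()}
        windows = sorted(
            promoter_window(g, 10_000, lengths[g.chrom]) for g in genes
        )
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert e1 <= s2
        assert all(e - s == 10_000 for s, e in windows)


class TestPromoterMethylation:
    def _records(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth_c1", "unmeth_c1",
                           "meth_t1", "unmeth_t1"],
        )
        return df

    def test_pooling_and_rates(self):
        # two cytosines in the window: control pooled (3+1)/(4+4)
        records = self._records(
            [
                ("chr1", 6_000, "+", "CpG", 3, 1, 1, 3),
                ("chr1", 7_000, "-", "CpG", 1, 3, 1, 3),
                ("chr1", 20_000, "+", "CpG", 9, 0, 9, 0),  # outside window
            ]
        )
        res = promoter_methylation(records, [_gene()], _sheet())
        row = res.loc["g1"]
        assert row["r_ctl"] == pytest.approx(0.5)
        assert row["r_tol"] == pytest.approx(0.25)
        assert row["fc_rate"] == pytest.approx(0.5)
        assert row["meth_class"] == "down"
        assert row["control_meth_count_sum"] == 4

    def test_equal_rates_unchanged_and_fc_count_one(self):
        records = self._records([("chr1", 6_000, "+", "CpG", 3, 1, 3, 1)])
        res = promoter_methylation(records, [_gene()], _sheet())
        assert res.loc["g1", "fc_rate"] == pytest.approx(1.0)
        assert res.loc["g1", "fc_count"] == pytest.approx(1.0)
        assert res.loc["g1", "meth_class"] == "unchanged"

    def test_gene_without_window_cytosines_is_uncovered(self):
        records = self._records([("chr1", 20_000, "+", "CpG", 3, 1, 3, 1)])
        res = promoter_methylation(records, [_gene()], _sheet())
        assert res.loc["g1", "meth_class"] == "uncovered"
        assert np.isnan(res.loc["g1", "p_meth"])

    def test_random_fixture_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for _ in range(20):
            pos = int(rng.integers(0, 30_000))
            rows.append(
                ("chr1", pos, rng.choice(["+", "-"]), rng.choice(["CpG", "CHG", "CHH"]),
                 int(rng.integers(0, 6)), int(rng.integers(0, 6)),
                 int(rng.integers(0, 6)), int(rng.integers(0, 6)))
            )
        records = self._records(rows)
        gene = _gene()
        res = promoter_methylation(records, [gene], _sheet())
        start, end = promoter_window(gene)
        oracle = window_sums_oracle(records, ["c1", "t1"], "chr1", start, end)
        m_ctl, t_ctl = oracle["c1"]
        m_tol, t_tol = oracle["t1"]
        assert res.loc["g1", "M_ctl"] == m_ctl and res.loc["g1", "T_ctl"] == t_ctl
        assert res.loc["g1", "M_tol"] == m_tol and res.loc["g1", "T_tol"] == t_tol
        if t_ctl and t_tol:
            expected_p = fisher_two_sided_oracle(m_tol, t_tol - m_tol, m_ctl, t_ctl - m_ctl)
            assert res.loc["g1", "p_meth"] == pytest.approx(expected_p, rel=1e-9)

    def test_demethylation_recovery_at_high_coverage(self):
        """Candidate promoters simulated at 0.4-fold CpG methylation come back
        with fc_rate near 0.4 when non-CpG methylation is off."""
        cfg = SimulationConfig(
            seed=21,
            n_genes=12,
            chrom_length=180_000,
            coverage_mean=50.0,
            n_up_spiked=0,
            n_down_spiked=0,
            n_candidate_spiked=4,
            demeth_effect=0.4,
            chg_meth_rate=0.0,
            chh_meth_rate=0.0,
        )
        data = simulate_dataset(cfg)
        res = promoter_methylation(
            data["methylation"], data["genes"], data["sheet"],
            chrom_lengths={c: len(s) for c, s in data["genome"].items()},
        )
        cand = data["truth"].query("label == 'candidate'").index
        fc = res.loc[cand, "fc_rate"]
        assert fc.to_numpy() == pytest.approx(0.4, abs=0.03)


class TestSummaries:
    def test_methylation_summary_percentages(self):
        res = pd.DataFrame(
            {"meth_class": ["up"] * 2 + ["down"] * 1 + ["unchanged"] * 6 + ["uncovered"]}
        )
        s = methylation_summary(res)
        assert s["n_covered"] == 9
        assert s["pct_up"] + s["pct_down"] + s["pct_unchanged"] == pytest.approx(100.0)
        assert s["pct_altered"] == pytest.approx(s["pct_up"] + s["pct_down"])

    def test_context_conservation_and_shares(self, small_dataset):
        reports = split_cytosine_reports(
            small_dataset["methylation"], small_dataset["sheet"].samples
        )
        summary = context_summary(reports)
        for sample, df in reports.items():
            n_meth = int((df["meth_count"] > 0).sum())
            assert summary.loc[sample, "total_methylated"] == n_meth
            shares = [summary.loc[sample, f"pct_{c}"] for c in ("CpG", "CHG", "CHH")]
            assert sum(shares) == pytest.approx(100.0)
            # CpG dominates at the default ~1% non-CpG rates
            assert shares[0] > 60 > max(shares[1:])

    def test_single_record_rate(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [4], "strand": ["+"], "meth_count": [3],
             "unmeth_count": [1], "context": ["CpG"]}
        )
        s = context_summary({"s1": df})
        assert s.loc["s1", "cpg_rate"] == pytest.approx(0.75)

    def test_all_unmethylated_flagged(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [4], "strand": ["+"], "meth_count": [0],
             "unmeth_count": [5], "context": ["CpG"]}
        )
        s = context_summary({"s1": df})
        assert s.loc["s1", "total_methylated"] == 0
        assert np.isnan(s.loc["s1", "pct_CpG"])
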