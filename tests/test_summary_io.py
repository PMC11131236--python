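"""Summary-statistics I/O, allele harmonization and proxy lookup."""

import numpy as np
import pandas as pd
import pytest

from metabomr import (
    SummaryStats,
    find_proxy,
    harmonize,
    harmonize_with_proxies,
    read_summary_stats,
    simulate_ld_panel,
)
from metabomr.errors import EmptyHarmonizationError, FormatError


def _stats(trait, rows):
    cols = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
    return SummaryStats(trait, pd.DataFrame(rows, columns=cols))


def _write(tmp_path, rows, name="stats.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]).to_csv(
        path, sep="\t", index=False)
    return path


GOOD_ROWS = [
    ("rs1", 1, 100, "A", "G", 0.3, 0.10, 0.02, 5.7e-7, 1000),
    ("rs2", 1, 200, "C", "T", 0.4, -0.05, 0.02, 0.0124, 1000),
    ("rs3", 1, 300, "G", "A", 0.2, 0.01, 0.02, 0.617, 1000),
]


class TestReadSummaryStats:
    def test_well_formed_file(self, tmp_path):
        stats = read_summary_stats(_write(tmp_path, GOOD_ROWS), trait="m")
        assert len(stats) == 3
        assert list(stats.df["snp"]) == ["rs1", "rs2", "rs3"]

    def test_invalid_rows_dropped(self, tmp_path, caplog):
        rows = GOOD_ROWS + [
            ("rs4", 1, 400, "A", "G", 0.3, 0.1, 0.0, 0.5, 1000),     # se = 0
            ("rs5", 1, 500, "AT", "G", 0.3, 0.1, 0.02, 0.5, 1000),   # multi-allelic
            ("rs6", 1, 600, "A", "G", 0.3, 0.1, 0.02, 1e-30, 1000),  # p inconsistent
        ]
        with caplog.at_level("INFO"):
            stats = read_summary_stats(_write(tmp_path, rows), trait="m")
        assert len(stats) == 3
        assert "dropped 3" in caplog.text

    def test_deterministic_reread(self, tmp_path):
        path = _write(tmp_path, GOOD_ROWS)
        a, b = read_summary_stats(path), read_summary_stats(path)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_dialect_renames_columns(self, tmp_path):
        path = tmp_path / "mapped.tsv"
        df = pd.DataFrame(GOOD_ROWS, columns=["rsid", "chrom", "bp", "a1", "a2",
                                              "freq", "b", "stderr", "pval", "size"])
        df.to_csv(path, sep="\t", index=False)
        dialect = {"snp": "rsid", "chr": "chrom", "pos": "bp", "ea": "a1", "oa": "a2",
                   "eaf": "freq", "beta": "b", "se": "stderr", "p": "pval", "n": "size"}
        assert len(read_summary_stats(path, dialect=dialect)) == 3

    def test_missing_column_and_empty_file_raise(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        pd.DataFrame({"snp": ["rs1"], "beta": [0.1]}).to_csv(bad, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_summary_stats(bad)
        empty = tmp_path / "empty.tsv"
        empty.write_text("snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\n")
        with pytest.raises(FormatError):
            read_summary_stats(empty)


class TestHarmonize:
    def test_allele_swap_flips_sign(self):
        exp = _stats("m", [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, np.nan, 1000)])
        out = _stats("o", [("rs1", 1, 100, "G", "A", 0.7, -0.05, 0.02, np.nan, 1000)])
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(0.05)
        assert h.df["ea"].iloc[0] == "A"

    def test_strand_flip_same_orientation(self):
        exp = _stats("m", [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, np.nan, 1000)])
        out = _stats("o", [("rs1", 1, 100, "T", "C", 0.3, 0.05, 0.02, np.nan, 1000)])
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped(self):
        exp = _stats("m", [("rs1", 1, 100, "A", "T", 0.50, 0.1, 0.02, np.nan, 1000),
                           ("rs2", 1, 200, "A", "G", 0.30, 0.1, 0.02, np.nan, 1000)])
        out = _stats("o", [("rs1", 1, 100, "A", "T", 0.50, 0.05, 0.02, np.nan, 1000),
                           ("rs2", 1, 200, "A", "G", 0.30, 0.05, 0.02, np.nan, 1000)])
        h = harmonize(exp, out)
        assert list(h.df["snp"]) == ["rs2"]

    def test_low_maf_palindrome_oriented_by_frequency(self):
        exp = _stats("m", [("rs1", 1, 100, "A", "T", 0.10, 0.1, 0.02, np.nan, 1000)])
        out = _stats("o", [("rs1", 1, 100, "A", "T", 0.88, 0.05, 0.02, np.nan, 1000)])
        h = harmonize(exp, out)
        # frequencies disagree on orientation -> outcome effect flipped
        assert h.df["beta_out"].iloc[0] == pytest.approx(-0.05)

    def test_idempotent_on_aligned_pair(self, strong_pair):
        exp, out = strong_pair
        h1 = harmonize(exp, out)
        realigned = SummaryStats(out.trait, out.df.copy())
        h2 = harmonize(exp, realigned)
        pd.testing.assert_frame_equal(h1.df, h2.df)

    def test_sign_consistency_under_full_outcome_flip(self, strong_pair):
        exp, out = strong_pair
        flipped = out.df.copy()
        flipped[["ea", "oa"]] = flipped[["oa", "ea"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, SummaryStats(out.trait, flipped))
        pd.testing.assert_frame_equal(h1.df, h2.df)

    def test_no_overlap_raises(self):
        exp = _stats("m", [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, np.nan, 1000)])
        out = _stats("o", [("rs9", 1, 900, "A", "G", 0.3, 0.1, 0.02, np.nan, 1000)])
        with pytest.raises(EmptyHarmonizationError):
            harmonize(exp, out)


class TestFindProxy:
    @pytest.fixture
    def panel(self):
        return simulate_ld_panel(1, 5, 0.95, seed=0, palindromic_fraction=0.0)

    def _outcome(self, panel, keep):
        df = panel.snps[panel.snps["snp"].isin(keep)].copy()
        df = df.rename(columns={"maf": "eaf"})
        df["beta"], df["se"], df["p"], df["n"] = 0.05, 0.02, np.nan, 1000.0
        return SummaryStats("o", df[["snp", "chr", "pos", "ea", "oa", "eaf",
                                     "beta", "se", "p", "n"]])

    def test_nearest_high_ld_neighbor_returned(self, panel):
        snps = list(panel.snps["snp"])
        out = self._outcome(panel, snps[1:])
        rec = find_proxy(snps[0], out, panel, r2_min=0.8)
        assert rec.proxy == snps[1]
        assert rec.r2 == pytest.approx(0.95**2)

    def test_threshold_excludes_weak_proxies(self, panel):
        snps = list(panel.snps["snp"])
        out = self._outcome(panel, snps[4:])  # best available r2 = 0.95^8 ~ 0.66
        assert find_proxy(snps[0], out, panel, r2_min=0.8) is None

    def test_distance_breaks_r2_ties(self):
        # uniform-correlation block: all pairs share r, only distance differs
        panel = simulate_ld_panel(1, 3, 0.9, seed=1, palindromic_fraction=0.0)
        panel.r[0, 2] = panel.r[2, 0] = 0.9
        snps = list(panel.snps["snp"])
        out = self._outcome(panel, snps[1:])
        assert find_proxy(snps[0], out, panel, r2_min=0.5).proxy == snps[1]

    def test_perfect_proxy_only_at_r2_min_one(self, panel):
        snps = list(panel.snps["snp"])
        out = self._outcome(panel, snps[1:])
        assert find_proxy(snps[0], out, panel, r2_min=1.0) is None


def test_proxy_substitution_carries_exposure_effect(strong_pair, small_panel):
    exp, out = strong_pair
    lead = exp.df.sort_values("p")["snp"].iloc[0]
    depleted = SummaryStats(out.trait, out.df[out.df["snp"] != lead])
    h = harmonize_with_proxies(exp.subset([lead]), depleted, small_panel, r2_min=0.8)
    row = h.df.iloc[0]
    assert row["snp"] == lead and row["proxy"]
    assert row["proxy_source"] != lead
    assert row["beta_exp"] == exp.df.set_index("snp").at[lead, "beta"]
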