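import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (FormatError, InputError, LDMatrix, harmonise,
                       instrument_strength, read_summary_stats,
                       select_instruments)
from mrmediate.gwas_io import (FLAG_DROPPED_PALINDROMIC, FLAG_FLIPPED,
                               FLAG_UNCHANGED)

from conftest import make_harmonised, make_sumstats

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def write_tsv(path, rows):
    path.write_text(HEADER + "".join(
        "\t".join(str(v) for v in r) + "\n" for r in rows))


ROWS = [
    ("rs1", 1, 1000, "A", "C", 0.3, 0.02, 0.005, 1e-9, 10000),
    ("rs2", 1, 2000, "G", "T", 0.4, -0.01, 0.004, 1e-3, 10000),
    ("rs3", 2, 5000, "C", "A", 0.2, 0.03, 0.006, 1e-12, 10000),
]


class TestReadSummaryStats:
    def test_well_formed_file_loads_all_rows(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_tsv(p, ROWS)
        ss = read_summary_stats(p, trait_name="bw")
        assert len(ss) == 3
        assert ss.load_report.n_dropped == 0
        assert list(ss.table["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_tsv(p, ROWS + [("rs4", 2, 6000, "A", "G", 0.1, 0.01, 0.0, 0.5, 10000)])
        ss = read_summary_stats(p)
        assert len(ss) == 3
        assert ss.load_report.n_dropped == 1
        assert ss.load_report.reasons["non_positive_se"] == 1

    def test_lowercase_alleles_normalised_without_rejection(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_tsv(p, [("rs1", 1, 1000, "a", "c", 0.3, 0.02, 0.005, 1e-9, 10000)])
        ss = read_summary_stats(p)
        assert ss.load_report.n_dropped == 0
        assert ss.table.loc[0, "effect_allele"] == "A"
        assert ss.table.loc[0, "other_allele"] == "C"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tP\tN\nrs1\t1\t1\tA\tC\t0.3\t0.1\t1e-9\t10\n")
        with pytest.raises(FormatError, match="SE"):
            read_summary_stats(p)

    def test_empty_file_is_an_input_error(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("")
        with pytest.raises(InputError):
            read_summary_stats(p)

    def test_custom_dialect(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("rsid\tchrom\tbp\ta1\ta2\tfreq\tb\tstderr\tpval\tsamples\n"
                     "rs1\t1\t1000\tA\tC\t0.3\t0.02\t0.005\t1e-9\t10000\n")
        dialect = {"variant_id": "rsid", "chrom": "chrom", "pos": "bp",
                   "effect_allele": "a1", "other_allele": "a2", "eaf": "freq",
                   "beta": "b", "se": "stderr", "pvalue": "pval", "n": "samples"}
        ss = read_summary_stats(p, dialect=dialect)
        assert len(ss) == 1

    def test_roundtrip_write_read(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_tsv(p, ROWS)
        ss = read_summary_stats(p)
        q = tmp_path / "out.tsv"
        ss.to_tsv(q)
        again = read_summary_stats(q)
        pd.testing.assert_frame_equal(ss.table, again.table)


class TestSelectInstruments:
    def test_nothing_significant_gives_empty_set(self):
        ss = make_sumstats(beta=[0.01] * 5, pvalue=[1e-4, 1e-5, 0.2, 1e-7, 0.5])
        assert len(select_instruments(ss)) == 0

    def test_ld_block_keeps_only_smallest_p(self):
        # 3 variants 1 kb apart, pairwise r2 = 0.5 >= 0.001: greedy keeps
        # only the smallest p (1e-10).
        ss = make_sumstats(beta=[0.05] * 3, pos=[1000, 2000, 3000],
                           pvalue=[1e-9, 1e-10, 1e-8])
        ld = LDMatrix(["rs1", "rs2", "rs3"],
                      np.array([[1, .5, .5], [.5, 1, .5], [.5, .5, 1.]]))
        out = select_instruments(ss, ld=ld)
        assert list(out.table["variant_id"]) == ["rs2"]

    def test_distance_rule_keeps_far_apart_variants(self):
        # 20,000 kb apart > 10,000 kb window: both retained
        ss = make_sumstats(beta=[0.05, 0.05], pos=[1_000_000, 21_000_000],
                           pvalue=[1e-9, 1e-9])
        out = select_instruments(ss)
        assert len(out) == 2

    def test_distance_rule_prunes_within_window(self):
        ss = make_sumstats(beta=[0.05, 0.05], pos=[1_000_000, 6_000_000],
                           pvalue=[1e-9, 1e-12])
        out = select_instruments(ss)
        assert list(out.table["variant_id"]) == ["rs2"]

    def test_window_boundary_is_inclusive(self):
        # exactly window_kb apart counts as inside the window
        ss = make_sumstats(beta=[0.05, 0.05], pos=[1_000_000, 11_000_000],
                           pvalue=[1e-12, 1e-9])
        assert len(select_instruments(ss)) == 1

    def test_ld_missing_significant_variant_is_error(self):
        ss = make_sumstats(beta=[0.05, 0.05], pos=[1000, 2000])
        ld = LDMatrix(["rs1"], np.array([[1.0]]))
        with pytest.raises(InputError, match="rs2"):
            select_instruments(ss, ld=ld)

    @settings(deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_row_order_invariance(self, rnd):
        rng = np.random.default_rng(5)
        n = 20
        ss = make_sumstats(
            beta=rng.normal(0, 0.05, n),
            pos=list(rng.integers(1, 50_000_000, n)),
            chrom=[str(c) for c in rng.integers(1, 4, n)],
            pvalue=list(rng.uniform(1e-12, 1e-6, n)))
        baseline = sorted(select_instruments(ss).table["variant_id"])
        idx = list(range(n))
        rnd.shuffle(idx)
        shuffled = make_sumstats(**{c: list(ss.table[c].iloc[idx])
                                    for c in ss.table.columns})
        assert sorted(select_instruments(shuffled).table["variant_id"]) == baseline

    def test_clump_output_mutually_independent(self):
        # exhaustive scan: retained pairs within the window have r2 < r2_max,
        # and every dropped significant variant conflicts with a retained one
        rng = np.random.default_rng(11)
        n = 12
        a = rng.normal(size=(n, 3))
        corr = np.corrcoef(a) ** 2
        np.fill_diagonal(corr, 1.0)
        ids = [f"rs{i + 1}" for i in range(n)]
        ld = LDMatrix(ids, corr)
        ss = make_sumstats(beta=[0.05] * n,
                           pos=list(rng.integers(1, 5_000_000, n)),
                           pvalue=list(rng.uniform(1e-12, 1e-9, n)))
        out = select_instruments(ss, r2_max=0.3, window_kb=10_000, ld=ld)
        kept = list(out.table["variant_id"])
        pos = dict(zip(ss.table["variant_id"], ss.table["pos"]))
        for i, u in enumerate(kept):
            for v in kept[i + 1:]:
                if abs(pos[u] - pos[v]) <= 10_000_000:
                    assert ld.lookup(u, v) < 0.3
        for v in set(ids) - set(kept):
            assert any(abs(pos[u] - pos[v]) <= 10_000_000
                       and ld.lookup(u, v) >= 0.3 for u in kept)


class TestHarmonise:
    def exposure(self):
        return make_sumstats("exp", beta=[0.05, 0.04, 0.03])

    def test_identical_coding_unchanged(self):
        exp = self.exposure()
        out = make_sumstats("out", beta=[0.2, 0.1, -0.1])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_UNCHANGED] * 3
        np.testing.assert_allclose(h.table["beta_out"], [0.2, 0.1, -0.1])

    def test_swapped_alleles_flip_sign(self):
        exp = make_sumstats("exp", beta=[0.05])
        out = make_sumstats("out", beta=[0.2], effect_allele=["C"],
                            other_allele=["A"], eaf=[0.7])
        h = harmonise(exp, out)
        assert h.table.loc[0, "flag"] == FLAG_FLIPPED
        assert h.table.loc[0, "beta_out"] == pytest.approx(-0.2)

    def test_strand_flip_resolved_by_complement(self):
        exp = make_sumstats("exp", beta=[0.05], effect_allele=["A"],
                            other_allele=["C"])
        out = make_sumstats("out", beta=[0.2], effect_allele=["T"],
                            other_allele=["G"])
        h = harmonise(exp, out)
        assert h.table.loc[0, "flag"] == FLAG_UNCHANGED
        assert h.table.loc[0, "beta_out"] == pytest.approx(0.2)

    def test_palindromic_mid_frequency_dropped(self):
        exp = make_sumstats("exp", beta=[0.05], effect_allele=["A"],
                            other_allele=["T"], eaf=[0.50])
        out = make_sumstats("out", beta=[0.2], effect_allele=["A"],
                            other_allele=["T"], eaf=[0.30])
        h = harmonise(exp, out)
        assert h.n_snp == 0
        assert h.provenance.loc[0, "flag"] == FLAG_DROPPED_PALINDROMIC

    def test_palindromic_aligned_by_eaf(self):
        exp = make_sumstats("exp", beta=[0.05], effect_allele=["A"],
                            other_allele=["T"], eaf=[0.2])
        # same labels but eaf on the other side of 0.5: strand flip implied
        out = make_sumstats("out", beta=[0.2], effect_allele=["A"],
                            other_allele=["T"], eaf=[0.8])
        h = harmonise(exp, out)
        assert h.n_snp == 1
        assert h.table.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert h.table.loc[0, "flag"] == FLAG_FLIPPED

    def test_irreconcilable_alleles_dropped_with_warning(self):
        exp = make_sumstats("exp", beta=[0.05], effect_allele=["A"],
                            other_allele=["C"])
        out = make_sumstats("out", beta=[0.2], effect_allele=["A"],
                            other_allele=["G"])
        with pytest.warns(UserWarning, match="irreconcilable"):
            h = harmonise(exp, out)
        assert h.n_snp == 0

    def test_missing_snps_flagged(self):
        exp = make_sumstats("exp", beta=[0.05, 0.04])
        out = make_sumstats("out", beta=[0.2])
        h = harmonise(exp.subset(["rs1", "rs2"]), out.subset(["rs1"]))
        assert h.n_snp == 1
        flags = dict(zip(h.provenance["variant_id"], h.provenance["flag"]))
        assert flags["rs2"] == "dropped_missing"

    def test_idempotence(self):
        exp = make_sumstats("exp", beta=[0.05, 0.04],
                            effect_allele=["A", "G"], other_allele=["C", "T"])
        out = make_sumstats("out", beta=[0.2, -0.3],
                            effect_allele=["C", "G"], other_allele=["A", "T"],
                            eaf=[0.7, 0.3])
        h1 = harmonise(exp, out)
        # rebuild the outcome in the exposure's coding and harmonise again
        out2 = make_sumstats("out", beta=list(h1.table["beta_out"]),
                             effect_allele=["A", "G"], other_allele=["C", "T"],
                             eaf=[0.3, 0.3])
        h2 = harmonise(exp, out2)
        assert list(h2.table["flag"]) == [FLAG_UNCHANGED] * 2
        np.testing.assert_allclose(h2.table["beta_out"], h1.table["beta_out"])

    @settings(deadline=None, derandomize=True)
    @given(beta=st.floats(-1, 1, allow_nan=False), eaf=st.floats(0.01, 0.99))
    def test_double_allele_swap_is_identity(self, beta, eaf):
        beta2, eaf2 = -(-beta), 1 - (1 - eaf)
        assert beta2 == beta and abs(eaf2 - eaf) < 1e-15


class TestInstrumentStrength:
    def test_forced_arithmetic(self):
        h = make_harmonised([0.02], [0.005], [0.1], [0.01])
        s = instrument_strength(h)
        assert s.f_per_snp.iloc[0] == pytest.approx(16.0)
        assert not s.weak

    def test_weak_flag(self):
        h = make_harmonised([0.01], [0.01], [0.1], [0.01])
        s = instrument_strength(h)
        assert s.mean_f == pytest.approx(1.0)
        assert s.weak

    def test_boundary_mean_f_of_10_is_weak(self):
        # F = 16 and 4 -> mean exactly 10: "exceeding 10" read strictly
        h = make_harmonised([0.02, 0.01], [0.005, 0.005], [0.1, 0.1],
                            [0.01, 0.01])
        s = instrument_strength(h)
        assert s.mean_f == pytest.approx(10.0)
        assert s.weak

    def test_empty_set_is_error(self):
        h = make_harmonised([], [], [], [])
        with pytest.raises(InputError):
            instrument_strength(h)
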