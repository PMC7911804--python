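"""STR diversity statistics: frequencies, PIC, He, Ho, FIS, panel summary."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedvar as pv
from pedvar import panels
from pedvar.genotypes import (GenotypeError, GenotypeTable, read_genotypes,
                              write_genepop, write_long_csv)
from pedvar.strstats import (allele_frequencies, expected_heterozygosity,
                             fis, heterozygosity, panel_summary, pic)


def _table(genotypes, locus="L1"):
    ids = [f"i{k}" for k in range(len(genotypes))]
    calls = np.array([[g] for g in genotypes], dtype=np.int32)
    return GenotypeTable(ids, [locus], calls)


class TestFrequencies:
    def test_simple_counts(self):
        t = _table([(87, 89), (89, 89)])
        freqs, n = allele_frequencies(t, "L1")
        assert n == 2
        assert freqs == {87: 0.25, 89: 0.75}

    def test_missing_excluded(self):
        t = _table([(0, 0), (87, 89)])
        freqs, n = allele_frequencies(t, "L1")
        assert n == 1
        assert freqs == {87: 0.5, 89: 0.5}

    def test_all_missing_rejected(self):
        t = _table([(0, 0)])
        with pytest.raises(GenotypeError):
            allele_frequencies(t, "L1")

    def test_generator_recovers_published_frequencies(self):
        # AHTk211 drawn at its published frequencies, n = 174
        ped = pv.Pedigree([pv.PedigreeRecord(f"d{i}") for i in range(174)])
        cfg = pv.GenotypeSimConfig(
            loci={"AHTk211": panels.locus_frequencies("AHTk211", renormalise=True)},
            seed=5)
        table = pv.simulate_genotypes(ped, cfg)
        freqs, n = allele_frequencies(table, "AHTk211")
        assert n == 174
        for a, p in panels.locus_frequencies("AHTk211", renormalise=True).items():
            se = np.sqrt(p * (1 - p) / (2 * 174))
            assert abs(freqs.get(a, 0.0) - p) <= 3 * se + 1e-9


class TestPicHe:
    def test_two_even_alleles(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375)
        assert expected_heterozygosity([0.25, 0.75]) == pytest.approx(0.375)

    def test_monomorphic(self):
        assert pic([1.0]) == 0.0
        assert expected_heterozygosity([1.0]) == 0.0

    def test_published_rows_within_rounding(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f211 = list(panels.locus_frequencies("AHTk211").values())
            assert pic(f211) == pytest.approx(0.477, abs=0.005)
            assert expected_heterozygosity(f211) == pytest.approx(0.570, abs=0.005)
            f171 = list(panels.locus_frequencies("AHT171").values())
            assert expected_heterozygosity(f171) == pytest.approx(0.773, abs=0.005)

    def test_unbiased_estimator_and_errors(self):
        assert expected_heterozygosity([0.5, 0.5], n=5, estimator="unbiased") \
            == pytest.approx(0.5 * 10 / 9)
        with pytest.raises(GenotypeError):
            expected_heterozygosity([0.5, 0.5], estimator="unbiased")
        with pytest.raises(GenotypeError):
            pic([-0.1, 1.1])

    def test_renormalisation_warns(self):
        with pytest.warns(UserWarning, match="renormalis"):
            pic([0.4, 0.4])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10))
    def test_pic_never_exceeds_he(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        assert pic(p) <= expected_heterozygosity(p) + 1e-12

    @pytest.mark.parametrize("k", range(2, 11))
    def test_he_maximised_at_uniform(self, k):
        assert expected_heterozygosity(np.full(k, 1 / k)) == pytest.approx(1 - 1 / k)


class TestHoFis:
    def test_all_homozygous(self):
        t = _table([(87, 87), (87, 87)])
        ho, he = heterozygosity(t, "L1")
        assert ho == 0.0 and he == 0.0

    def test_fis_zero_and_published_rows(self):
        assert fis(0.5, 0.5) == 0.0
        assert fis(0.580, 0.570) == pytest.approx(-0.018, abs=0.0005)
        assert fis(0.793, 0.725) == pytest.approx(-0.094, abs=0.0005)

    def test_fis_undefined_warns(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert np.isnan(fis(0.0, 0.0))

    def test_random_mating_fis_near_zero_wahlund_positive(self):
        rng = np.random.default_rng(12)
        n = 200
        # random mating at p = 0.5
        null_fis = []
        for _ in range(50):
            g = rng.integers(0, 2, size=(n, 1, 2)).astype(np.int32) + 87
            t = GenotypeTable([f"i{k}" for k in range(n)], ["L"], g)
            ho, he = heterozygosity(t, "L")
            null_fis.append(fis(ho, he))
        se = np.std(null_fis, ddof=1) / np.sqrt(len(null_fis))
        assert abs(np.mean(null_fis)) <= 3 * se + 0.01
        # two diverged subpopulations pooled: heterozygote deficit
        a = np.where(rng.random((n // 2, 1, 2)) < 0.9, 87, 89)
        b = np.where(rng.random((n // 2, 1, 2)) < 0.1, 87, 89)
        t = GenotypeTable([f"i{k}" for k in range(n)], ["L"],
                          np.concatenate([a, b]).astype(np.int32))
        ho, he = heterozygosity(t, "L")
        assert fis(ho, he) > 0.2


class TestPanelSummary:
    def test_single_locus_means(self):
        t = _table([(87, 89), (89, 89), (87, 89)])
        summary = panel_summary(t)
        row = summary.loci[0]
        assert summary.mean("pic") == row.pic
        assert summary.total_alleles == 2

    def test_published_column_means(self):
        stats = panels.printed_locus_stats()
        assert stats["PIC"].mean() == pytest.approx(0.597, abs=0.0005)
        assert stats["Ho"].mean() == pytest.approx(0.656, abs=0.0005)
        assert stats["FIS"].mean() == pytest.approx(-0.018, abs=0.0005)

    def test_simulated_panel_he_within_binomial_bounds(self):
        ped = pv.Pedigree([pv.PedigreeRecord(f"d{i}") for i in range(174)])
        table = pv.simulate_genotypes(ped, pv.GenotypeSimConfig(seed=3))
        summary = panel_summary(table)
        printed = panels.printed_locus_stats()
        for row in summary.loci:
            he_pub = printed.loc[row.locus, "He"]
            se = np.sqrt(he_pub * (1 - he_pub) / 174)
            assert abs(row.he - he_pub) <= 3 * se + 0.01


class TestGenotypeIO:
    def test_long_csv_two_dogs(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("id,locus,allele1,allele2\nd1,L1,87,89\nd2,L1,91,91\n")
        t = read_genotypes(p, format="long_csv")
        assert t.n_individuals == 2
        assert t.locus_calls("L1").shape == (2, 2)

    def test_genepop_missing_convention(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("title\nL1\nL2\nPop\nd1 , 087089 000000\nd2 , 091091 087087\n")
        t = read_genotypes(p, format="genepop")
        assert not t.typed_mask("L2")[0]
        assert t.typed_mask("L2")[1]

    def test_genepop_malformed_line_numbered(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("title\nL1\nPop\nd1 , 08709\n")
        with pytest.raises(GenotypeError, match="line"):
            read_genotypes(p, format="genepop")

    def test_genepop_wrong_locus_count(self, tmp_path):
        p = tmp_path / "g.gen"
        p.write_text("title\nL1\nL2\nPop\nd1 , 087089\n")
        with pytest.raises(GenotypeError, match="loci"):
            read_genotypes(p, format="genepop")

    def test_full_roundtrip(self, tmp_path):
        ped = pv.simulate_pedigree(pv.polish_greyhound_config(seed=9))
        sample = ped.ids[:174]
        table = pv.simulate_genotypes(
            ped, pv.GenotypeSimConfig(missing_rate=0.02, sample_ids=sample, seed=9))
        path = tmp_path / "t.gen"
        write_genepop(table, path)
        assert read_genotypes(path, format="genepop") == table
        path2 = tmp_path / "t.csv"
        write_long_csv(table, path2)
        assert read_genotypes(path2, format="long_csv") == table
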