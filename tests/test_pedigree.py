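"""Pedigree model, I/O, founders, completeness and breeding statistics."""

import numpy as np
import pandas as pd
import pytest

import pedvar as pv
from pedvar.pedigree import (Pedigree, PedigreeError, PedigreeRecord,
                             classify_matings, completeness,
                             generation_interval, identify_founders,
                             litter_statistics, progeny_statistics,
                             read_pedigree, write_pedigree)

from conftest import random_small_pedigree


def _write(tmp_path, text):
    p = tmp_path / "ped.csv"
    p.write_text(text)
    return p


class TestReadValidate:
    def test_trio_roundtrip(self, tmp_path):
        path = _write(tmp_path, "id,sire,dam\nA,NN,NN\nB,,0\nC,A,B\n")
        ped = read_pedigree(path)
        assert len(ped) == 3
        assert ped.record("A").both_parents_unknown
        assert ped.record("B").both_parents_unknown   # "" and "0" normalised
        assert ped.record("C").sire_id == "A"
        # topological: parents before offspring
        order = list(ped.topo)
        assert order.index(ped.index_of("A")) < order.index(ped.index_of("C"))

    def test_self_parent_rejected(self, tmp_path):
        path = _write(tmp_path, "id,sire,dam\nC,C,NN\n")
        with pytest.raises(PedigreeError, match="self-parent"):
            read_pedigree(path)

    def test_duplicate_id_named(self, tmp_path):
        path = _write(tmp_path, "id,sire,dam\nA,NN,NN\nA,NN,NN\n")
        with pytest.raises(PedigreeError, match="'A'"):
            read_pedigree(path)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree([PedigreeRecord("A", "B", None),
                      PedigreeRecord("B", "A", None)])

    def test_missing_parent_error_or_phantom(self, tmp_path):
        path = _write(tmp_path, "id,sire,dam\nC,X,NN\n")
        with pytest.raises(PedigreeError, match="'X'"):
            read_pedigree(path)
        ped = read_pedigree(path, on_missing_parent="create")
        assert "X" in ped and ped.record("X").sex == "M"

    def test_sex_and_year_consistency(self):
        with pytest.raises(PedigreeError, match="sex"):
            Pedigree([PedigreeRecord("A", sex="F"),
                      PedigreeRecord("B", "A", None)])
        with pytest.raises(PedigreeError, match="older"):
            Pedigree([PedigreeRecord("A", birth_year=2010),
                      PedigreeRecord("B", "A", None, birth_year=2005)])

    def test_write_read_roundtrip_synthetic(self, tmp_path):
        ped = pv.simulate_pedigree(pv.polish_greyhound_config(seed=5))
        assert len(ped) == 912
        path = tmp_path / "full.csv"
        write_pedigree(ped, path)
        back = read_pedigree(path)
        assert back.to_frame().equals(ped.to_frame())


class TestFounders:
    def test_trio_founder_sets(self, trio):
        rep = identify_founders(trio)
        assert rep.founders_any_unknown == {"A", "B"}
        assert rep.founders_both_unknown == {"A", "B"}

    def test_one_unknown_split(self):
        ped = Pedigree([PedigreeRecord("A", sex="M"),
                        PedigreeRecord("H", "A", None)])
        rep = identify_founders(ped)
        assert "H" in rep.founders_any_unknown
        assert "H" not in rep.founders_both_unknown

    def test_planted_counts_recovered(self):
        ped = pv.simulate_pedigree(pv.polish_greyhound_config(seed=1))
        rep = identify_founders(ped)
        assert rep.n_any_unknown == 83
        assert rep.n_both_unknown == 27

    def test_partition_of_records(self):
        ped = random_small_pedigree(3)
        rep = identify_founders(ped)
        both = rep.founders_both_unknown
        one = rep.founders_any_unknown - both
        non = set(ped.ids) - rep.founders_any_unknown
        assert len(both) + len(one) + len(non) == len(ped)
        assert all(ped.record(i).sire_id and ped.record(i).dam_id for i in non)


class TestCompleteness:
    def test_trivial_depths(self, trio):
        comp = completeness(trio)
        by = dict(zip(comp.ids, zip(comp.max_generations,
                                    comp.complete_generations,
                                    comp.equivalent_complete_generations)))
        assert by["A"] == (0, 0, 0.0)
        assert by["C"] == (1, 1, 1.0)

    def test_half_known_parentage(self):
        ped = Pedigree([PedigreeRecord("A"), PedigreeRecord("H", "A", None)])
        comp = completeness(ped)
        i = comp.ids.index("H")
        assert comp.max_generations[i] == 1
        assert comp.complete_generations[i] == 0
        assert comp.equivalent_complete_generations[i] == 0.5

    def test_t_monotone_when_parent_added(self):
        # revealing an unknown parent can only increase every t
        base = [PedigreeRecord("A"), PedigreeRecord("B"),
                PedigreeRecord("C", "A", None), PedigreeRecord("D", "C", "B")]
        t0 = completeness(Pedigree(base)).equivalent_complete_generations
        richer = [PedigreeRecord("A"), PedigreeRecord("B"), PedigreeRecord("Z"),
                  PedigreeRecord("C", "A", "Z"), PedigreeRecord("D", "C", "B")]
        ped1 = Pedigree(richer)
        comp1 = completeness(ped1)
        t1 = {i: t for i, t in zip(comp1.ids, comp1.equivalent_complete_generations)}
        ped0 = Pedigree(base)
        t0 = {i: t for i, t in zip(ped0.ids, completeness(ped0).equivalent_complete_generations)}
        assert all(t1[i] >= t0[i] for i in t0)


class TestGenerationInterval:
    def test_mean_of_pair_ages(self, trio):
        res = generation_interval(trio)
        assert res["mean"] == pytest.approx(5.0)     # ages 6 and 4
        assert res["n_pairs"] == 2

    def test_single_pair_degenerate_se(self):
        ped = Pedigree([PedigreeRecord("A", birth_year=2000),
                        PedigreeRecord("B", "A", None, birth_year=2004)])
        res = generation_interval(ped)
        assert res["se"] == 0.0 and res["degenerate"]

    def test_no_dated_pairs(self):
        ped = Pedigree([PedigreeRecord("A"), PedigreeRecord("B", "A", None)])
        with pytest.raises(PedigreeError, match="no dated"):
            generation_interval(ped)

    def test_simulated_mean_recovered(self):
        cfg = pv.PedigreeSimConfig(n_total=700, n_founders_both_unknown=60,
                                   n_founders_one_unknown=0, years=40,
                                   founder_year_span=9, first_litter_year=10,
                                   mean_parent_age=5.0, seed=11)
        ped = pv.simulate_pedigree(cfg)
        res = generation_interval(ped)
        assert abs(res["mean"] - 5.0) <= 2 * res["se"] + 0.05


class TestMatings:
    def test_full_sib_mating(self, full_sib_family):
        rep = classify_matings(full_sib_family)
        assert rep.count("full_sib") == 1
        assert rep.offspring["full_sib"] == 1

    def test_parent_offspring_precedence(self):
        # dam is also the sire's mother: parent-offspring, not sib
        ped = Pedigree([
            PedigreeRecord("G", sex="F"), PedigreeRecord("H", sex="M"),
            PedigreeRecord("S", "H", "G", sex="M"),
            PedigreeRecord("X", "S", "G")])
        rep = classify_matings(ped)
        assert rep.count("parent_offspring") == 1
        assert rep.count("full_sib") == rep.count("half_sib") == 0

    def test_half_sib_mating(self):
        ped = Pedigree([
            PedigreeRecord("S", sex="M"), PedigreeRecord("D1", sex="F"),
            PedigreeRecord("D2", sex="F"),
            PedigreeRecord("A", "S", "D1", sex="M"),
            PedigreeRecord("B", "S", "D2", sex="F"),
            PedigreeRecord("X", "A", "B")])
        assert classify_matings(ped).count("half_sib") == 1

    def test_planted_matings_percentages(self):
        ped = pv.simulate_pedigree(pv.polish_greyhound_config(seed=2))
        rep = classify_matings(ped)
        assert rep.count("full_sib") == 2
        assert rep.percentage("full_sib") == pytest.approx(100 * 2 / 912)
        assert round(rep.percentage("full_sib"), 2) == 0.22


class TestLittersProgeny:
    def test_single_litter(self):
        recs = [PedigreeRecord("S", sex="M", birth_year=2000),
                PedigreeRecord("D", sex="F", birth_year=2000)]
        recs += [PedigreeRecord(f"P{i}", "S", "D", birth_year=2003) for i in range(4)]
        rep = litter_statistics(Pedigree(recs))
        assert rep.litter_sizes == [4]
        assert rep.full_sib_group_sizes == [4]

    def test_group_vs_litter_split(self):
        recs = [PedigreeRecord("S", sex="M", birth_year=2000),
                PedigreeRecord("D", sex="F", birth_year=2000)]
        recs += [PedigreeRecord(f"A{i}", "S", "D", birth_year=2003) for i in range(2)]
        recs += [PedigreeRecord(f"B{i}", "S", "D", birth_year=2005) for i in range(3)]
        rep = litter_statistics(Pedigree(recs))
        assert rep.full_sib_group_sizes == [5]
        assert rep.litter_sizes == [2, 3]

    def test_simulated_litter_range_and_mean(self):
        # pooled over several replicates the generator realises the full
        # configured range 2..16 and the target mean
        sizes = []
        for seed in range(4):
            ped = pv.simulate_pedigree(pv.polish_greyhound_config(seed=seed))
            sizes.extend(litter_statistics(ped).litter_sizes)
        assert min(sizes) == 2 and max(sizes) == 16
        assert abs(np.mean(sizes) - 6.0) < 0.5

    def test_progeny_trio(self, trio):
        rep = progeny_statistics(trio)
        assert rep.n_breeders == 2
        assert rep.n_zero_progeny == 1

    def test_all_founders_no_offspring(self):
        ped = Pedigree([PedigreeRecord(f"F{i}") for i in range(5)])
        rep = progeny_statistics(ped)
        assert rep.n_breeders == 0
        assert rep.n_zero_progeny == 5

    def test_breeders_match_parent_reference_tally(self):
        ped = random_small_pedigree(7)
        rep = progeny_statistics(ped)
        used = {r.sire_id for r in ped.records} | {r.dam_id for r in ped.records}
        used.discard(None)
        assert rep.n_breeders == len(used)
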