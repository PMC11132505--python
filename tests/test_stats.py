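import numpy as np
import pandas as pd
import pytest

from lcdscope.errors import ConfigurationError, ConsistencyError
from lcdscope.proteome import ProteinRecord, Proteome
from lcdscope.scanner import LCD
from lcdscope.stats import (ClassCountTable, co_occurrence_counts,
                            count_class_table, domain_specific_classes,
                            max_single_clan_share, organism_level_frequency,
                            per_residue_occupancy, rarity_category,
                            secondary_share, spatially_distinct)


def lcd_frame(rows):
    return pd.DataFrame(rows, columns=["accession", "class_label", "start", "end"])


def make_table(class_counts, n_proteins=10, n_residues=1000, domain="Eukaryota",
               pid="ORG1"):
    per_class = pd.DataFrame.from_dict(
        class_counts, orient="index",
        columns=["n_proteins_with_lcd", "n_lcds", "n_lcd_residues"])
    per_class.index.name = "class_label"
    return ClassCountTable(pid, per_class, n_proteins, n_residues, domain)


class TestCountClassTable:
    def test_no_lcds_all_zero(self):
        proteome = Proteome("P", [ProteinRecord("a", "M" * 40)])
        table = count_class_table(lcd_frame([]), proteome)
        assert len(table.per_class) == 0
        assert table.n_proteins_total == 1
        assert table.n_residues_total == 40

    def test_single_lcd_residue_count(self):
        proteome = Proteome("P", [ProteinRecord("a", "Q" * 40)])
        table = count_class_table(lcd_frame([("a", "Q", 1, 20)]), proteome)
        assert table.count("Q", "n_lcd_residues") == 20
        assert table.count("Q", "n_proteins_with_lcd") == 1

    def test_overlapping_lcds_counted_once(self):
        proteome = Proteome("P", [ProteinRecord("a", "Q" * 40)])
        table = count_class_table(
            lcd_frame([("a", "Q", 1, 20), ("a", "Q", 11, 30)]), proteome)
        assert table.count("Q", "n_lcd_residues") == 30
        assert table.count("Q", "n_lcds") == 2
        assert table.count("Q", "n_proteins_with_lcd") == 1

    def test_unknown_accession_raises(self):
        proteome = Proteome("P", [ProteinRecord("a", "Q" * 40)])
        with pytest.raises(ConsistencyError):
            count_class_table(lcd_frame([("ghost", "Q", 1, 20)]), proteome)

    def test_counts_satisfy_invariants_on_random_tables(self, rng):
        proteome = Proteome("P", [ProteinRecord(f"p{i}", "Q" * 100)
                                  for i in range(8)])
        rows = []
        for _ in range(40):
            acc = f"p{int(rng.integers(0, 8))}"
            s = int(rng.integers(1, 80))
            rows.append((acc, str(rng.choice(["Q", "QN", "N"])), s, s + 19))
        table = count_class_table(lcd_frame(rows), proteome)
        for lbl in table.per_class.index:
            assert table.count(lbl, "n_proteins_with_lcd") <= table.n_proteins_total
            assert table.count(lbl, "n_lcd_residues") <= table.n_residues_total
            assert table.count(lbl, "n_lcds") >= table.count(lbl, "n_proteins_with_lcd")


class TestOrganismLevelFrequency:
    def test_half_the_organisms(self):
        tables = [make_table({"HQ": (1, 1, 20)}, pid=f"O{i}") for i in range(2)]
        tables += [make_table({}, pid=f"O{i+2}") for i in range(2)]
        freqs = organism_level_frequency(tables, ["HQ", "QN"])
        assert freqs["HQ"] == 50.0
        assert freqs["QN"] == 0.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            organism_level_frequency([], ["Q"])

    def test_matches_direct_enumeration_and_order_invariant(self, rng):
        labels = ["Q", "N", "HQ"]
        tables = []
        for i in range(12):
            counts = {lbl: (int(rng.integers(0, 3)), 1, 10) for lbl in labels
                      if rng.random() < 0.6}
            tables.append(make_table(counts, pid=f"O{i}"))
        freqs = organism_level_frequency(tables, labels)
        for lbl in labels:
            expected = 100.0 * sum(
                1 for t in tables if t.count(lbl, "n_proteins_with_lcd") >= 1
            ) / len(tables)
            assert freqs[lbl] == pytest.approx(expected)
        shuffled = [tables[i] for i in rng.permutation(len(tables))]
        assert organism_level_frequency(shuffled, labels).equals(freqs)


class TestRarityCategory:
    @pytest.mark.parametrize("x, expected", [
        (0.0, "absent"), (0.1, "very rare"), (4.999, "very rare"),
        (5.0, "rare"), (19.999, "rare"), (20.0, "normal"),
        (49.999, "normal"), (50.0, "common"), (74.999, "common"),
        (75.0, "very common"), (100.0, "very common"),
    ])
    def test_bin_boundaries(self, x, expected):
        assert rarity_category(x) == expected

    def test_out_of_range_raises(self):
        for x in (-0.1, 100.1):
            with pytest.raises(ValueError):
                rarity_category(x)

    def test_bins_partition_the_range(self):
        # every grid value falls in exactly one bin
        for x in np.linspace(0, 100, 2001):
            assert rarity_category(float(x)) in {
                "absent", "very rare", "rare", "normal", "common", "very common"}


class TestPerResidueOccupancy:
    def test_examples(self):
        table = make_table({"Q": (1, 1, 20)}, n_residues=40)
        assert per_residue_occupancy(table, "Q") == 50.0
        assert per_residue_occupancy(table, "N") == 0.0

    def test_full_occupancy_is_hundred(self):
        table = make_table({"Q": (1, 1, 60)}, n_proteins=1, n_residues=60)
        assert per_residue_occupancy(table, "Q") == 100.0

    def test_empty_proteome_raises(self):
        table = make_table({}, n_proteins=0, n_residues=0)
        with pytest.raises(ValueError):
            per_residue_occupancy(table, "Q")


class TestSecondaryShare:
    def test_two_classes(self):
        table = make_table({"HQ": (2, 3, 60), "HP": (1, 1, 20)})
        shares = secondary_share(table, "H")
        assert shares["HQ"] == 75.0
        assert shares["HP"] == 25.0

    def test_single_class_is_hundred(self):
        shares = secondary_share(make_table({"HQ": (1, 2, 40)}), "H")
        assert shares["HQ"] == 100.0

    def test_zero_denominator_is_undefined(self):
        assert secondary_share(make_table({"H": (1, 1, 20)}), "H") is None

    def test_random_counts_sum_to_hundred(self, rng):
        counts = {"N" + s: (1, int(rng.integers(1, 10)), 20)
                  for s in "ACDEFG"}
        shares = secondary_share(make_table(counts), "N")
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)


class TestDomainSpecificClasses:
    def freqs(self, euk, arch=1.0, bact=0.0, vir=1.9):
        return {
            "Eukaryota": pd.Series({"HL": euk}),
            "Archaea": pd.Series({"HL": arch}),
            "Bacteria": pd.Series({"HL": bact}),
            "Viruses": pd.Series({"HL": vir}),
        }

    def test_included(self):
        assert domain_specific_classes(self.freqs(16.0), "Eukaryota") == {"HL"}

    def test_boundary_out_max_excluded(self):
        assert domain_specific_classes(self.freqs(16.0, arch=2.0), "Eukaryota") == set()

    def test_boundary_in_min_excluded(self):
        assert domain_specific_classes(self.freqs(15.0), "Eukaryota") == set()

    def test_missing_domain_raises(self):
        with pytest.raises(ConfigurationError):
            domain_specific_classes({"Eukaryota": pd.Series({"HL": 16.0})},
                                    "Bacteria")


class TestCoOccurrence:
    def test_reciprocal_merge(self):
        lcds = lcd_frame([("p1", "CS", 1, 20), ("p1", "SC", 30, 49)])
        assert co_occurrence_counts(lcds) == {("CS|SC",): 1}

    def test_exact_combination_counts(self):
        lcds = lcd_frame([
            ("p1", "CR", 1, 20), ("p1", "CS", 30, 49),
            ("p2", "CR", 1, 20), ("p2", "SC", 30, 49),
            ("p3", "CS", 1, 20),
        ])
        counts = co_occurrence_counts(lcds)
        assert counts[("CR|RC", "CS|SC")] == 2
        assert counts[("CS|SC",)] == 1

    def test_matches_per_protein_enumeration(self, rng):
        from lcdscope.classes import reciprocal_merged_label
        labels = ["CR", "CS", "SC", "Q", "QH", "HQ"]
        rows = [(f"p{int(rng.integers(0, 10))}", str(rng.choice(labels)),
                 1, 20) for _ in range(60)]
        lcds = lcd_frame(rows)
        counts = co_occurrence_counts(lcds)
        expected = {}
        for acc in set(r[0] for r in rows):
            cats = tuple(sorted({reciprocal_merged_label(r[1])
                                 for r in rows if r[0] == acc}))
            expected[cats] = expected.get(cats, 0) + 1
        assert counts == expected


class TestSpatiallyDistinct:
    def make(self, start, end, acc="p1"):
        return LCD(acc, "HQ", start, end, "X" * (end - start + 1), {})

    def test_nested_is_not_distinct(self):
        assert not spatially_distinct(self.make(1, 50), self.make(10, 30))

    def test_adjacent_full_length_is_distinct(self):
        assert spatially_distinct(self.make(1, 20), self.make(21, 40))

    def test_partial_overlap_with_enough_outside(self):
        assert spatially_distinct(self.make(1, 30), self.make(25, 50))

    def test_different_proteins_raise(self):
        with pytest.raises(ValueError):
            spatially_distinct(self.make(1, 20), self.make(21, 40, acc="p2"))


class TestMaxSingleClanShare:
    def test_share_of_dominant_clan(self):
        proteins = {f"p{i}" for i in range(10)}
        clans = {f"p{i}": "CL0001" for i in range(6)}
        clans.update({f"p{i}": f"CL000{i}" for i in range(6, 10)})
        assert max_single_clan_share(proteins, clans) == 60.0

    def test_below_minimum_is_undefined(self):
        proteins = {"p1", "p2", "p3", "p4"}
        clans = {p: "CL0001" for p in proteins}
        assert max_single_clan_share(proteins, clans) is None

    def test_unannotated_proteins_excluded_from_denominator(self):
        proteins = {f"p{i}" for i in range(10)}
        clans = {f"p{i}": "CL0001" for i in range(5)}  # 5 annotated, all one clan
        assert max_single_clan_share(proteins, clans) == 100.0

    def test_matches_brute_force_counting(self, rng):
        proteins = {f"p{i}" for i in range(30)}
        clans = {p: f"CL{int(rng.integers(1, 5)):04d}" for p in proteins
                 if rng.random() < 0.7}
        got = max_single_clan_share(proteins, clans)
        annotated = [p for p in proteins if p in clans]
        if len(annotated) < 5:
            assert got is None
        else:
            best = max(sum(1 for p in annotated if clans[p] == c)
                       for c in set(clans.values()))
            assert got == pytest.approx(100.0 * best / len(annotated))
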