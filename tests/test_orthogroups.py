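from collections import Counter

import numpy as np
import pytest

from wgdscope.orthogroups import (
    OrthogroupRecord,
    cafe_prefilter,
    classify_pattern,
    count_patterns,
    duplication_enrichment,
    expanded_filter,
    read_genecount_table,
)

SPECIES = ("Pant", "Pkai", "Pest")


def rec(og, pant, pkai, pest):
    return OrthogroupRecord(og, {"Pant": pant, "Pkai": pkai, "Pest": pest})


COUNT_TABLE = """\
Orthogroup\tPant\tPkai\tPest
OG1\t2\t1\t1
OG2\t1\t1\t1
OG3\t5\t1\t0
"""


class TestReadGenecountTable:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text(COUNT_TABLE)
        records = read_genecount_table(p)
        assert [r.og_id for r in records] == ["OG1", "OG2", "OG3"]
        assert records[2].counts == {"Pant": 5, "Pkai": 1, "Pest": 0}

    def test_total_column_ignored(self, tmp_path):
        plain = tmp_path / "a.tsv"
        with_total = tmp_path / "b.tsv"
        plain.write_text(COUNT_TABLE)
        with_total.write_text(
            "Orthogroup\tPant\tPkai\tPest\tTotal\n"
            "OG1\t2\t1\t1\t4\nOG2\t1\t1\t1\t3\nOG3\t5\t1\t0\t6\n"
        )
        assert [r.counts for r in read_genecount_table(plain)] == [
            r.counts for r in read_genecount_table(with_total)
        ]

    def test_all_zero_row_rejected(self, tmp_path):
        p = tmp_path / "z.tsv"
        p.write_text("Orthogroup\tPant\tPkai\tPest\nOG1\t0\t0\t0\n")
        with pytest.raises(ValueError):
            read_genecount_table(p)

    def test_non_integer_count_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Orthogroup\tPant\tPkai\tPest\nOG1\t1\tx\t1\n")
        with pytest.raises(ValueError, match="row 2"):
            read_genecount_table(p)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "counts, label",
        [((2, 1, 1), "2:1:1"), ((1, 1, 1), "1:1:1"), ((5, 1, 0), "multi:1:0")],
    )
    def test_labels(self, counts, label):
        assert classify_pattern(rec("x", *counts), SPECIES).label == label

    def test_missing_species_is_error(self):
        r = OrthogroupRecord("x", {"Pant": 1})
        with pytest.raises(KeyError):
            classify_pattern(r, SPECIES)


class TestCountPatterns:
    def test_counts_partition_the_table(self):
        rng = np.random.default_rng(12)
        records = [
            rec(f"og{i}", *(int(c) for c in row))
            for i, row in enumerate(rng.integers(0, 5, size=(500, 3)))
            if row.sum() > 0
        ]
        table = count_patterns(records, SPECIES)
        assert table["count"].sum() == len(records)
        # independent tally oracle
        oracle = Counter(
            classify_pattern(r, SPECIES).label for r in records
        )
        assert dict(zip(table.label, table["count"])) == dict(oracle)

    def test_single_record_is_hundred_percent(self):
        table = count_patterns([rec("og", 1, 1, 1)], SPECIES)
        assert table.percent.iloc[0] == 100.0


class TestDuplicationEnrichment:
    def test_symmetric_duplication_gives_unit_odds(self):
        # equal per-species duplication rates: 20 duplicated orthogroups each
        records = (
            [rec(f"a{i}", 2, 1, 1) for i in range(20)]
            + [rec(f"b{i}", 1, 2, 1) for i in range(20)]
            + [rec(f"c{i}", 1, 1, 2) for i in range(20)]
            + [rec(f"d{i}", 1, 1, 1) for i in range(200)]
        )
        res = duplication_enrichment(records, "Pant", ("Pkai", "Pest"))
        assert res["odds_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_focal_excess_detected(self):
        records = (
            [rec(f"a{i}", 2, 1, 1) for i in range(300)]
            + [rec(f"b{i}", 1, 2, 1) for i in range(30)]
            + [rec(f"c{i}", 1, 1, 2) for i in range(30)]
            + [rec(f"d{i}", 1, 1, 1) for i in range(2000)]
        )
        res = duplication_enrichment(records, "Pant", ("Pkai", "Pest"))
        assert res["odds_ratio"] > 1
        assert res["ci_low"] > 1
        assert res["p_value"] < 1e-4

    def test_p_matches_hypergeometric_enumeration(self):
        # exhaustive enumeration over all tables with the margins of
        # [[8, 2], [1, 5]]
        from math import comb

        a, b, c, d = 8, 2, 1, 5
        n, row1, col1 = a + b + c + d, a + b, a + c
        probs = {}
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            probs[x] = (
                comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)
            )
        p_oracle = sum(p for x, p in probs.items() if p <= probs[a] * (1 + 1e-12))

        records = (
            [rec(f"a{i}", 2, 1, 1) for i in range(a)]
            + [rec(f"b{i}", 1, 2, 1) for i in range(c)]
            + [rec(f"d{i}", 1, 1, 1) for i in range(2)]
        )
        res = duplication_enrichment(records, "Pant", ("Pkai", "Pest"))
        # cross-check the scipy p on the stated table directly
        from scipy.stats import fisher_exact

        assert fisher_exact([[8, 2], [1, 5]])[1] == pytest.approx(
            p_oracle, abs=1e-12
        )
        assert 0 <= res["p_value"] <= 1

    def test_degenerate_margin_does_not_crash(self):
        # every focal-present orthogroup is duplicated: b and c cells are 0
        records = [rec(f"a{i}", 2, 1, 1) for i in range(5)]
        res = duplication_enrichment(records, "Pant", ("Pkai", "Pest"))
        assert res["degenerate"]
        assert 0 <= res["p_value"] <= 1


class TestExpandedFilter:
    def test_strict_inequality_boundary(self):
        records = [rec("keep", 5, 2, 2), rec("drop", 4, 2, 2)]
        assert expanded_filter(records, "Pant", ("Pkai", "Pest")) == ["keep"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(13)
        records = [
            rec(f"og{i}", *(int(c) for c in row))
            for i, row in enumerate(rng.integers(0, 8, size=(200, 3)))
            if row.sum() > 0
        ]
        got = expanded_filter(records, "Pant", ("Pkai", "Pest"))
        oracle = [
            r.og_id
            for r in records
            if r.counts["Pant"] > 2 * r.counts["Pkai"]
            and r.counts["Pant"] > 2 * r.counts["Pest"]
        ]
        assert got == oracle

    def test_retained_set_consistent_with_pattern_classes(self):
        rng = np.random.default_rng(14)
        records = [
            rec(f"og{i}", *(int(c) for c in row))
            for i, row in enumerate(rng.integers(0, 6, size=(300, 3)))
            if row.sum() > 0
        ]
        kept = set(expanded_filter(records, "Pant", ("Pkai", "Pest")))
        for r in records:
            if r.og_id in kept:
                cls = classify_pattern(r, SPECIES)
                assert cls.pattern[0] in ("multi", "2")


class TestCafePrefilter:
    SP5 = ("Pant", "Pkai", "Pest", "Pcan", "Lsax")

    def rec5(self, og, *counts):
        return OrthogroupRecord(og, dict(zip(self.SP5, counts)))

    def test_increase_and_presence_criteria(self):
        records = [
            self.rec5("keep", 6, 2, 3, 1, 1),
            self.rec5("zero", 6, 2, 3, 0, 1),   # a zero count
            self.rec5("small", 5, 3, 3, 1, 1),  # increase of 2 only
        ]
        assert cafe_prefilter(records, "Pant") == ["keep"]

    def test_matches_hand_scan_on_random_rows(self):
        rng = np.random.default_rng(15)
        records = [
            self.rec5(f"og{i}", *(int(c) for c in row))
            for i, row in enumerate(rng.integers(0, 9, size=(50, 5)))
            if row.sum() > 0
        ]
        got = cafe_prefilter(records, "Pant")
        oracle = [
            r.og_id
            for r in records
            if r.counts["Pant"] - max(
                v for k, v in r.counts.items() if k != "Pant"
            ) >= 3
            and min(r.counts.values()) >= 1
        ]
        assert got == oracle

    def test_external_significance_flag_applies(self):
        records = [self.rec5("a", 6, 2, 3, 1, 1), self.rec5("b", 7, 2, 3, 1, 1)]
        assert cafe_prefilter(records, "Pant", significant={"b": True}) == ["b"]
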