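import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from virowinnow import winnow
from virowinnow.homology import HomologyHit, ProteinRecord
from virowinnow.seqtools import random_dna, revcomp


def _mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


@pytest.fixture(scope="module")
def genomes():
    rng = np.random.default_rng(21)
    return {f"KV-{i}": random_dna(1200, rng) for i in range(3)}


class TestMatchKnownViruses:
    def test_two_percent_divergence_matches(self, genomes):
        rng = np.random.default_rng(1)
        frag = _mutate(genomes["KV-1"][100:500], 0.02, rng)
        bins, unmatched = winnow.match_known_viruses([("q", frag)], genomes)
        assert [m.query_id for m in bins["KV-1"]] == ["q"]
        assert not unmatched
        assert bins["KV-1"][0].nucleotide_identity >= 95.0

    def test_high_divergence_unmatched(self, genomes):
        rng = np.random.default_rng(2)
        frag = _mutate(genomes["KV-1"][100:500], 0.12, rng)
        bins, unmatched = winnow.match_known_viruses([("q", frag)], genomes)
        assert unmatched == [("q", frag)]

    def test_reverse_complement_matches(self, genomes):
        frag = revcomp(genomes["KV-2"][300:700])
        bins, _ = winnow.match_known_viruses([("q", frag)], genomes)
        assert [m.query_id for m in bins["KV-2"]] == ["q"]

    def test_bin_totals_match_generator_truth(self, genomes):
        # oracle: fragments are built from known genomes with error rates
        # far from the 95% boundary, so the truth is the construction
        rng = np.random.default_rng(3)
        items, expected = [], {label: 0 for label in genomes}
        n_unmatched = 0
        for i in range(30):
            label = f"KV-{i % 3}"
            start = int(rng.integers(0, 700))
            frag = genomes[label][start : start + 400]
            if i % 5 == 0:
                frag = _mutate(frag, 0.15, rng)
                n_unmatched += 1
            else:
                frag = _mutate(frag, 0.01, rng)
                expected[label] += 1
            items.append((f"q{i}", frag))
        bins, unmatched = winnow.match_known_viruses(items, genomes)
        assert {k: len(v) for k, v in bins.items()} == expected
        assert len(unmatched) == n_unmatched

    def test_partition(self, genomes):
        rng = np.random.default_rng(4)
        items = [("a", genomes["KV-0"][:400]), ("b", random_dna(400, rng))]
        bins, unmatched = winnow.match_known_viruses(items, genomes)
        assert sum(len(v) for v in bins.values()) + len(unmatched) == len(items)


class TestApplyExclusions:
    def _hit(self, e, taxon="NonPhageVirus", subject="v"):
        return HomologyHit("q", subject, 1, 100, 50, e, 90, 90, taxon)

    def _db(self):
        return {
            "v": ProteinRecord("v", "MKL", "NonPhageVirus", "insect virus"),
            "pv": ProteinRecord(
                "pv", "MKL", "NonPhageVirus", "some plant virus", plant_host=True
            ),
            "fungus": ProteinRecord("fungus", "MKL", "Fungi", "a fungus"),
        }

    def test_short_with_strong_virus_hit_excluded_under_length_rule(self):
        items = [("c1", "A" * 99)]
        retained, tally = winnow.apply_exclusions(items, {"c1": self._hit(1e-40)}, self._db())
        assert not retained and tally["short"] == 1

    def test_plant_virus_rule(self):
        items = [("c1", "A" * 500)]
        retained, tally = winnow.apply_exclusions(
            items, {"c1": self._hit(1e-40, subject="pv")}, self._db()
        )
        assert not retained and tally["plant_virus"] == 1

    def test_no_hit_rule(self):
        items = [("c1", "A" * 500)]
        retained, tally = winnow.apply_exclusions(items, {"c1": None}, self._db())
        assert not retained and tally["no_match"] == 1

    def test_weak_hit_counts_as_no_match(self):
        items = [("c1", "A" * 500)]
        retained, tally = winnow.apply_exclusions(items, {"c1": self._hit(1e-5)}, self._db())
        assert tally["no_match"] == 1  # strict threshold

    def test_non_virus_rule(self):
        items = [("c1", "A" * 500)]
        retained, tally = winnow.apply_exclusions(
            items, {"c1": self._hit(1e-40, taxon="Fungi", subject="fungus")}, self._db()
        )
        assert not retained and tally["non_virus"] == 1

    def test_partition_exact(self):
        items = [(f"c{i}", "A" * (90 + i * 10)) for i in range(8)]
        rehits = {
            "c0": None,
            "c1": self._hit(1e-40),  # 100 nt, retained
            "c2": self._hit(1e-4),
            "c3": self._hit(1e-40, subject="pv"),
            "c4": self._hit(1e-40, taxon="Fungi", subject="fungus"),
            "c5": self._hit(1e-40),
            "c6": None,
            "c7": self._hit(1e-40),
        }
        retained, tally = winnow.apply_exclusions(items, rehits, self._db())
        assert sum(tally.values()) == len(items)
        assert tally["retained"] == len(retained) == 3


class TestClassifyAndRank:
    def test_representation_class_counts_positive_libraries(self):
        rows = [
            winnow.ContigCountRow("c1", (1, 0, 2, 0), ("L1", "L2", "L3", "L4"), 500, 3),
            winnow.ContigCountRow("c2", (5, 5, 5, 5), ("L1", "L2", "L3", "L4"), 900, 20),
        ]
        records = winnow.classify_and_rank(rows)
        by_name = {r.designation: r for r in records}
        assert by_name["c1"].representation_class == "2-of-4"
        assert by_name["c2"].representation_class == "4-of-4"
        assert by_name["c2"].high_likelihood and not by_name["c1"].high_likelihood
        assert by_name["c2"].rank == 1  # larger singleton total ranks first

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="no member reads"):
            winnow.ContigCountRow("c", (0, 0, 0, 0), ("L1", "L2", "L3", "L4"), 100, 0)
            winnow.classify_and_rank(
                [winnow.ContigCountRow("c", (0, 0, 0, 0), ("L1", "L2", "L3", "L4"), 100, 0)]
            )

    def test_count_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="counts sum"):
            winnow.ContigCountRow("c", (1, 2, 3, 4), ("L1", "L2", "L3", "L4"), 100, 11)

    def test_sort_order(self):
        libs = ("L1", "L2", "L3", "L4")
        rows = [
            winnow.ContigCountRow("small", (1, 1, 1, 1), libs, 100, 4),
            winnow.ContigCountRow("big", (50, 0, 0, 0), libs, 100, 50),
            winnow.ContigCountRow("wide", (13, 13, 12, 12), libs, 100, 50),
        ]
        order = [r.designation for r in winnow.classify_and_rank(rows)]
        assert order == ["wide", "big", "small"]  # total desc, then libraries desc


class TestTable2Fixture:
    def test_row_property_holds_for_all_38_rows(self):
        rows = winnow.load_table2()
        assert len(rows) == 38
        for row in rows:
            assert sum(row.library_counts) == row.singletons_total

    def test_class_sizes_and_sums(self):
        records = winnow.classify_and_rank(winnow.load_table2())
        classes = winnow.class_summary(records)
        assert classes["4-of-4"] == (15, 46845)
        assert classes["3-of-4"] == (9, 1276)
        assert classes["2-of-4"] == (8, 927)
        assert classes["1-of-4"] == (6, 5180)

    def test_four_of_four_flagged(self):
        records = winnow.classify_and_rank(winnow.load_table2())
        flagged = [r for r in records if r.high_likelihood]
        assert len(flagged) == 15
        assert all(all(c > 0 for c in r.library_counts) for r in flagged)


class TestFractions:
    def test_printed_percentages(self):
        assert winnow.pct(292499, 876528) == 33.4
        assert winnow.pct(230555, 292499) == 78.8
        assert winnow.pct(54228, 55677) == 97.4
        assert winnow.pct(46845, 55677, ndigits=0) == 84.0

    def test_zero_denominator_undefined(self):
        assert winnow.pct(5, 0) is None
        report = winnow.summarize_fractions({"non_host_total": 0, "non_phage_virus": 0})
        assert report.as_dict()["non_phage_virus/non_host"]["percent"] is None

    def test_half_up_rounding(self):
        assert winnow.pct(5, 1000) == 0.5
        assert winnow.pct(1, 16, ndigits=1) == 6.3  # 6.25 rounds half-up

    @given(st.integers(0, 10**6), st.integers(1, 10**6))
    def test_pct_matches_decimal_oracle(self, num, den):
        from decimal import ROUND_HALF_UP, Decimal

        expected = float(
            (Decimal(num) * 100 / Decimal(den)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        assert winnow.pct(num, den) == expected

    def test_summarize_fractions_known_totals(self):
        counts = winnow.load_fig2_counts()
        report = winnow.summarize_fractions(counts).as_dict()
        assert report["known_virus_matched/non_phage"]["numerator"] == 230555
        assert report["known_virus_matched/non_phage"]["percent"] == 78.8


def test_table1_sums():
    sums = winnow.table1_library_sums()
    assert sums == {"SAL_1": 46, "SAL_2": 53, "SAL_3": 44, "SAL_4": 39}
    assert sum(sums.values()) == 182
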