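"""Read-level tandem detection: span rule, error tolerance, best-unit choice."""

from itertools import product

import numpy as np
import pytest

from oracles import oracle_scan_read
from satrate import canonical_unit, count_reads, count_sample, filter_units, scan_read
from satrate.counter import AbundanceTable, counts_to_table, relatedness_graph

import pandas as pd


def make_read(unit: str, copies: int, flank_after: str = "") -> str:
    return unit * copies + flank_after


def breaking_flank(unit: str, rng, length: int = 60) -> str:
    """Random flank whose first bases cannot extend a tandem stretch of
    ``unit`` (starts with three bases absent from the unit)."""
    absent = [b for b in "ACGT" if b not in unit]
    lead = (absent[0] * 3) if absent else "N" * 3
    return lead + "".join(rng.choice(list("ACGT"), length - 3))


class TestScanRead:
    def test_perfect_dinucleotide_fills_read(self):
        (hit,) = scan_read("AC" * 75)
        assert hit.unit.sequence == "AC"
        assert hit.copies == 75
        assert hit.span == (0, 150)
        assert hit.mismatches == 0

    def test_49bp_stretch_below_min_span_not_counted(self, rng):
        read = ("AG" * 24 + "A" + breaking_flank("AG", rng, 101))[:150]
        assert scan_read(read) == []

    def test_50bp_stretch_is_counted(self, rng):
        read = ("AG" * 25 + breaking_flank("AG", rng, 100))[:150]
        (hit,) = scan_read(read)
        assert hit.unit.sequence == "AG"
        assert hit.span[1] - hit.span[0] == 50

    def test_single_substitution_tolerated_per_copy(self):
        read = list("AAGAG" * 30)
        read[32] = "T" if read[32] != "T" else "C"  # inside copy 7
        (hit,) = scan_read("".join(read))
        assert hit.unit.sequence == canonical_unit("AAGAG").sequence
        assert hit.copies == 30
        assert hit.mismatches == 1

    def test_single_base_insertion_between_copies(self):
        (hit,) = scan_read("AAGAG" * 10 + "T" + "AAGAG" * 15)
        assert hit.copies == 25
        assert hit.mismatches == 0

    def test_read_shorter_than_min_span_is_empty(self):
        assert scan_read("ACACAC") == []

    def test_n_bases_break_stretches(self):
        read = "AC" * 30 + "N" + "AC" * 30  # 60 bp either side of the N
        hits = scan_read(read)
        assert len(hits) == 2
        assert all(h.unit.sequence == "AC" for h in hits)
        spans = sorted(h.span for h in hits)
        assert spans[0][1] <= 60 and spans[1][0] >= 61

    def test_spans_never_overlap(self, rng):
        for _ in range(50):
            bases = rng.choice(list("ACGT"), 150)
            # plant two arrays of one unit
            bases[0:60] = list("ACG" * 20)
            bases[80:140] = list("ACG" * 20)
            hits = scan_read("".join(bases))
            spans = sorted(h.span for h in hits)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_exhaustive_perfect_arrays_all_short_units(self):
        """Perfect arrays of every 2-, 3- and 4-mer are recovered with the
        planted canonical unit and exact copy count."""
        for n in (2, 3, 4):
            for tup in product("ACGT", repeat=n):
                unit = "".join(tup)
                canon = canonical_unit(unit).sequence
                k = len(canon)
                reps = 150 // n
                read = unit * reps
                hits = scan_read(read)
                assert len(hits) == 1, unit
                assert hits[0].unit.sequence == canon
                assert hits[0].copies == len(read) // k


class TestOracleAgreement:
    def test_planted_arrays_with_errors_match_exhaustive_oracle(self, rng):
        """On reads with planted arrays and up to 1% error, the reported
        unit matches the exhaustive-alignment oracle exactly and copies
        agree within one."""
        units = ["AC", "AAG", "AAGAG", "ACTGCC", "AATGG"]
        mismatch_unit = 0
        for i in range(120):
            unit = units[i % len(units)]
            copies = int(rng.integers(60 // len(unit) + 1, 150 // len(unit) + 1))
            arr = list(unit * copies)
            for j in range(len(arr)):
                if rng.random() < 0.01:
                    arr[j] = str(rng.choice([b for b in "ACGT" if b != arr[j]]))
            pos = int(rng.integers(0, 151 - len(arr)))
            read = list(rng.choice(list("ACGT"), 150))
            read[pos : pos + len(arr)] = arr
            read = "".join(read)
            mine = scan_read(read)
            ref = oracle_scan_read(read)
            if ref is None:
                assert mine == []
                continue
            canon, ref_copies, _cov = ref
            assert mine, read
            assert mine[0].unit.sequence == canon
            assert abs(sum(h.copies for h in mine) - ref_copies) <= 1
        assert mismatch_unit == 0


class TestCountSample:
    def test_counts_sum_over_reads(self):
        assert count_reads(["AT" * 75] * 10) == {"AT": 750}

    def test_single_best_unit_per_read(self):
        # 80 bp of AC and 70 bp of AG on one read: larger span wins outright
        assert count_reads(["AC" * 40 + "AG" * 35]) == {"AC": 40}

    def test_empty_fastq_gives_empty_row(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        row = count_sample(p, sample="s")
        assert row.empty

    def test_fastq_roundtrip_counting(self, tmp_path):
        p = tmp_path / "reads.fastq"
        with open(p, "w") as fh:
            for i in range(10):
                fh.write(f"@r{i}\n{'AT' * 75}\n+\n{'I' * 150}\n")
        row = count_sample(p, sample="s")
        assert row.to_dict() == {"AT": 750.0}

    def test_malformed_fastq_names_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\n")  # truncated record
        with pytest.raises(ValueError, match="index 1"):
            count_sample(p)


class TestFilterUnits:
    def make_table(self, cols):
        df = pd.DataFrame(cols, index=[f"L{i}" for i in range(14)])
        return AbundanceTable(values=df.astype(float), normalized=True)

    def test_min_copy_boundary(self):
        t = self.make_table({"below": [9.0] * 14, "edge": [9.0] * 13 + [10.0]})
        retained, _ = filter_units(t)
        assert retained.units == ["edge"]

    def test_common_mean_boundary(self):
        t = self.make_table(
            {"almost": [99.9] * 14, "common": [100.0] * 14}
        )
        retained, common = filter_units(t)
        assert set(retained.units) == {"almost", "common"}
        assert common.units == ["common"]

    def test_all_zero_table(self):
        t = self.make_table({"a": [0.0] * 14, "b": [0.0] * 14})
        retained, common = filter_units(t)
        assert retained.units == [] and common.units == []

    def test_empty_table(self):
        t = AbundanceTable(values=pd.DataFrame(), normalized=False)
        retained, common = filter_units(t)
        assert retained.values.empty and common.values.empty


class TestRelatednessGraph:
    def test_substitution_edge(self):
        g = relatedness_graph(["AAG", "AAC"])
        assert g.edges[("AAC", "AAG")]["edge_type"] == "substitution"

    def test_indel_edge(self):
        g = relatedness_graph(["AAAG", "AAAGG"])
        assert g.edges[("AAAG", "AAAGG")]["edge_type"] == "indel/copy"

    def test_rotation_strand_merge_single_node(self):
        g = relatedness_graph(["AC", "GT"])
        assert list(g.nodes) == ["AC"]
        assert g.number_of_edges() == 0

    def test_duplication_edge(self):
        # AAGAAC (canonical AACAAG) is AAG doubled with one substitution
        g = relatedness_graph(["AAG", "AAGAAC"])
        assert g.edges[("AAG", "AACAAG")]["edge_type"] == "indel/copy"

    def test_abundance_ranks(self):
        g = relatedness_graph(["AAG", "AAC"], abundances={"AAG": 5.0, "AAC": 50.0})
        assert g.nodes["AAC"]["abundance_rank"] == 1
        assert g.nodes["AAG"]["abundance_rank"] == 2


def test_counts_to_table_fills_missing_with_zero():
    rows = [
        pd.Series({"AC": 10.0}, name="s1"),
        pd.Series({"AAG": 5.0}, name="s2"),
    ]
    t = counts_to_table(rows)
    assert t.values.loc["s1", "AAG"] == 0.0
    assert t.values.loc["s2", "AC"] == 0.0
    assert not t.normalized
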