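import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_promoter, random_seq
from oracles import str_calls_oracle
from promoscan.promoter_io import revcomp
from promoscan.str_scanner import (
    StrCall,
    canonicalize,
    frequency_table,
    is_primitive,
    scan_strs,
    unit_count_summary,
    unit_gc_class,
)

TABLE_MOTIF_FAMILIES = [
    "AC", "AT", "AG", "AGG", "AAT", "CCG", "AAC", "AGC", "AAAT", "AAAG",
    "CG", "ATCCC", "AAAC", "AAGG", "AAG", "ACC", "AGAGG", "ATCC", "ACGGC",
    "AAGGG",
]


def brute_canonical(motif: str) -> str:
    rc = revcomp(motif)
    cands = [motif[i:] + motif[:i] for i in range(len(motif))]
    cands += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(cands)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "motif,expected",
        [("GT", "AC"), ("AC", "AC"), ("GGGGT", "ACCCC"), ("CT", "AG"),
         ("TG", "AC"), ("CGG", "CCG")],
    )
    def test_known_families(self, motif, expected):
        assert brute_canonical(motif) == expected  # oracle agrees
        assert canonicalize(motif) == expected

    def test_reference_motif_families_are_fixed_points(self):
        for m in TABLE_MOTIF_FAMILIES:
            assert canonicalize(m) == m

    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_rotation_and_strand_invariance(self, motif):
        if not is_primitive(motif):
            return
        canon = canonicalize(motif)
        for i in range(len(motif)):
            rot = motif[i:] + motif[:i]
            assert canonicalize(rot) == canon
        assert canonicalize(revcomp(motif)) == canon
        assert canonicalize(canon) == canon  # idempotent

    @pytest.mark.parametrize("bad", ["GG", "AGAG", "A", "ACGTACG", "ANT"])
    def test_contract_violations(self, bad):
        with pytest.raises(ValueError):
            canonicalize(bad)


class TestScan:
    def test_pentanucleotide_worked_example(self):
        calls = scan_strs(make_promoter("GGGGT" * 6))
        assert len(calls) == 1
        c = calls[0]
        assert (c.period, c.units, c.canonical_motif) == (5, 6, "ACCCC")
        assert (c.interval.start, c.interval.end) == (0, 30)

    def test_below_six_units_not_called(self):
        seq = "TTGCA" + "AC" * 5 + "A" + "GTTCA"  # 5.5 units
        assert scan_strs(make_promoter(seq)) == []

    def test_mononucleotide_runs_excluded(self):
        assert scan_strs(make_promoter("G" * 12)) == []
        assert scan_strs(make_promoter("T" * 40)) == []

    def test_n_breaks_runs(self):
        seq = "AC" * 6 + "N" + "AC" * 6
        calls = scan_strs(make_promoter(seq))
        assert [(c.interval.start, c.interval.end) for c in calls] == [
            (0, 12), (13, 25)
        ]

    def test_adjacent_different_motifs_counted_separately(self):
        seq = "AT" * 6 + "TG" * 6
        calls = scan_strs(make_promoter(seq))
        assert len(calls) == 2
        assert calls[0].canonical_motif == "AT"
        assert calls[1].canonical_motif == "AC"  # TG family
        assert calls[0].interval.end <= calls[1].interval.start

    def test_left_run_extended_greedily_on_shared_base(self):
        # AC run whose trailing C also starts a CT-periodic stretch
        seq = "AC" * 6 + "TCTCTCTCTCTCT"
        calls = scan_strs(make_promoter(seq))
        starts_ends = [(c.interval.start, c.interval.end) for c in calls]
        assert starts_ends[0] == (0, 12)
        # right run begins at or after the left run's reported end
        for s, e in starts_ends[1:]:
            assert s >= 12

    def test_primitive_period_only(self):
        # (AG)x12 must be one period-2 call, never a period-4 (AGAG) call
        calls = scan_strs(make_promoter("AG" * 12))
        assert len(calls) == 1
        assert calls[0].period == 2
        assert calls[0].units == 12

    def test_partial_trailing_unit_excluded(self):
        calls = scan_strs(make_promoter("CCAAT" + "AGC" * 7 + "AG" + "TTT"))
        (c,) = calls
        assert c.units == 7
        assert c.interval.length == 21

    def test_gc_class_only_for_trinucleotides(self):
        calls = scan_strs(make_promoter("AGC" * 6 + "TT" + "AC" * 6))
        tri = [c for c in calls if c.period == 3]
        di = [c for c in calls if c.period == 2]
        assert tri[0].gc_class == "67%GC"
        assert di[0].gc_class is None

    @pytest.mark.parametrize("gc", [0.4, 0.5, 0.6])
    def test_oracle_equivalence_random_sequences(self, rng, gc):
        for _ in range(25):
            seq = random_seq(rng, 2000, gc=gc)
            got = [
                (c.interval.start, c.interval.end, c.period, c.units,
                 c.observed_motif)
                for c in scan_strs(make_promoter(seq))
            ]
            assert got == str_calls_oracle(seq)

    def test_oracle_equivalence_repeat_dense(self, rng):
        # sequences stitched from repeat fragments exercise overlap trimming
        units = ["AC", "AG", "AT", "AGC", "AAT", "AAAT", "GGGGT", "CT", "TG"]
        for _ in range(60):
            parts = []
            while sum(len(x) for x in parts) < 400:
                u = units[rng.integers(len(units))]
                reps = int(rng.integers(1, 16))
                parts.append(u * reps)
                if rng.random() < 0.5:
                    parts.append(random_seq(rng, int(rng.integers(1, 8))))
            seq = "".join(parts)[:400]
            got = [
                (c.interval.start, c.interval.end, c.period, c.units,
                 c.observed_motif)
                for c in scan_strs(make_promoter(seq))
            ]
            assert got == str_calls_oracle(seq)

    def test_calls_are_perfect_repeats(self, rng):
        seq = random_seq(rng, 2000, gc=0.5)
        for c in scan_strs(make_promoter(seq)):
            sub = seq[c.interval.start : c.interval.end]
            assert sub == c.observed_motif * c.units
            assert is_primitive(c.observed_motif)


class TestFrequencyTable:
    def test_even_split(self):
        calls = [
            StrCall("g", __import__("promoscan").Interval(i * 20, i * 20 + 12),
                    2, 6, m, m, 2000)
            for i, m in enumerate(["AC"] * 5 + ["AT"] * 5)
        ]
        tab = frequency_table(calls, n_promoters=20)
        assert tab.freq_percent["AC"] == pytest.approx(50.0)
        assert tab.freq_percent["AT"] == pytest.approx(50.0)
        assert tab.str_per_seq == pytest.approx(0.5)

    def test_single_call_is_100_percent(self):
        from promoscan import Interval

        tab = frequency_table(
            [StrCall("g", Interval(0, 12), 2, 6, "AC", "AC", 2000)], 1
        )
        assert tab.freq_percent["AC"] == pytest.approx(100.0)

    def test_empty_calls(self):
        tab = frequency_table([], n_promoters=10)
        assert tab.total == 0
        assert tab.str_per_seq == 0.0

    def test_reference_table_reproduces_frequencies(self):
        # packaged counts reproduce their own percent column within 0.1
        from promoscan.reference import reference_table

        tab = reference_table("chicken_promoter")
        assert tab.freq_percent["AC"] == pytest.approx(
            100 * 405 / tab.total, abs=1e-9
        )
        assert abs(tab.freq_percent.sum() - 100.0) < 1e-9


class TestUnitCountSummary:
    def _call(self, period, units):
        from promoscan import Interval

        unit = {2: "AC", 3: "AGC", 4: "AAAT", 5: "AAAAT"}.get(period, "AAAAAT")
        unit = unit[:period]
        return StrCall("g", Interval(0, period * units), period, units,
                       unit, canonicalize(unit), 2000)

    def test_di_mean(self):
        s = unit_count_summary([self._call(2, u) for u in (6, 6, 8)])
        assert s.mean_units[2] == pytest.approx(6.6667, abs=1e-3)

    def test_missing_period_flagged_undefined(self):
        s = unit_count_summary([self._call(2, 6)])
        assert s.mean_units[5] is None
        assert s.n_calls[5] == 0

    def test_contrast_samples_partition(self):
        calls = [self._call(2, 6), self._call(4, 8), self._call(6, 7),
                 self._call(3, 6)]
        s = unit_count_summary(calls)
        assert s.di_units == [6]
        assert sorted(s.tetra_plus_units) == [7, 8]


def test_gc_class_mapping():
    assert unit_gc_class("AAT") == "0%GC"
    assert unit_gc_class("AGC") == "67%GC"
    assert unit_gc_class("CCG") == "100%GC"
    assert unit_gc_class("ACT") == "33%GC"
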