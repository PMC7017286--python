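"""Filtering rules, complexity metrics, cross-correlation and JSD."""

import math

import numpy as np
import pytest

from equichip.errors import (
    ConfigurationError,
    IncompleteReportError,
    NoSignalError,
    UndefinedMetricError,
)
from equichip.readqc import (
    QCThresholds,
    TagSet,
    complexity_metrics,
    cross_correlation,
    filter_alignments,
    jsd_fingerprint,
    jsd_from_pmfs,
    mark_pcr_duplicates,
    qc_verdict,
    remove_duplicates,
)

from conftest import make_tag, tagset


class TestFilterAlignments:
    def test_mapq_boundary(self):
        kept, stats = filter_alignments(tagset(make_tag(mapq=29), make_tag(mapq=30)))
        assert len(kept) == 1
        assert kept.df["mapq"].iloc[0] == 30
        assert stats["low_mapq"] == 1

    def test_empty_input(self):
        kept, stats = filter_alignments(tagset())
        assert len(kept) == 0
        assert all(v == 0 for v in stats.values())

    def test_hand_enumerated_mixture(self):
        tags = [make_tag(start=i * 100, end=i * 100 + 50, unmapped=True) for i in range(2)]
        tags += [make_tag(start=300, end=350, secondary=True)]
        tags += [make_tag(start=400, end=450, qc_fail=True)]
        tags += [make_tag(start=i * 100 + 500, end=i * 100 + 550, mapq=10) for i in range(2)]
        tags += [make_tag(start=i * 100 + 800, end=i * 100 + 850) for i in range(4)]
        kept, stats = filter_alignments(tagset(*tags))
        assert len(kept) == 4
        assert stats == {"unmapped": 2, "secondary": 1, "qc_fail": 1,
                         "optical_duplicate": 0, "low_mapq": 2}

    def test_first_matching_criterion_wins(self):
        kept, stats = filter_alignments(tagset(make_tag(unmapped=True, mapq=0)))
        assert stats["unmapped"] == 1 and stats["low_mapq"] == 0


class TestDeduplication:
    def test_exact_triplicate_keeps_one(self):
        marked = mark_pcr_duplicates(tagset(*[make_tag(start=100, end=150)] * 3))
        assert marked.df["pcr_duplicate"].sum() == 2
        assert len(remove_duplicates(marked)) == 1

    def test_strand_distinct_overlap_retained(self):
        plus = make_tag(start=100, end=150, strand="+")
        minus = make_tag(start=100, end=150, strand="-")
        marked = mark_pcr_duplicates(tagset(plus, minus))
        assert marked.df["pcr_duplicate"].sum() == 0

    def test_all_distinct_none_flagged(self):
        marked = mark_pcr_duplicates(tagset(*[make_tag(start=s, end=s + 50)
                                              for s in range(0, 500, 60)]))
        assert marked.df["pcr_duplicate"].sum() == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 50, size=200)
        ts = TagSet.from_arrays(["chr1"] * 200, starts, starts + 50,
                                np.where(rng.random(200) < 0.5, "+", "-"))
        once = mark_pcr_duplicates(ts)
        twice = mark_pcr_duplicates(once)
        assert (once.df["pcr_duplicate"] == twice.df["pcr_duplicate"]).all()

    def test_minus_strand_key_uses_five_prime_end(self):
        # same span start but different ends: distinct minus-strand 5' ends
        a = make_tag(start=100, end=150, strand="-")
        b = make_tag(start=100, end=151, strand="-")
        assert mark_pcr_duplicates(tagset(a, b)).df["pcr_duplicate"].sum() == 0


class TestComplexity:
    def test_hand_counted_multiset(self):
        tags = []
        for mult, pos in zip((1, 1, 1, 1, 2, 4), range(0, 600, 100)):
            tags += [make_tag(start=pos, end=pos + 50)] * mult
        report = complexity_metrics(tagset(*tags))
        assert report.total_tags == 10 and report.distinct_positions == 6
        assert report.NRF == pytest.approx(0.6)
        assert report.PBC1 == pytest.approx(4 / 6)
        assert report.PBC2 == pytest.approx(4.0)

    def test_all_distinct_degenerate_case(self):
        report = complexity_metrics(tagset(*[make_tag(start=s, end=s + 50)
                                             for s in range(0, 300, 60)]))
        assert report.NRF == 1.0 and report.PBC1 == 1.0
        assert math.isinf(report.PBC2)

    def test_empty_library_rejected(self):
        with pytest.raises(UndefinedMetricError):
            complexity_metrics(tagset())

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(1, 120))
            pos = rng.integers(0, 30, size=n) * 10
            strand = np.where(rng.random(n) < 0.5, "+", "-")
            ts = TagSet.from_arrays(["chr1"] * n, pos, pos + 50, strand)
            report = complexity_metrics(ts)
            # independent oracle: sort-and-count the key multiset
            keys = sorted((p if s == "+" else p + 50, s) for p, s in zip(pos, strand))
            from collections import Counter
            mult = Counter(keys)
            assert report.distinct_positions == len(mult)
            assert report.positions_one_read == sum(v == 1 for v in mult.values())
            assert report.positions_two_reads == sum(v == 2 for v in mult.values())


class TestCrossCorrelation:
    def test_exact_translation_recovers_shift(self):
        """Minus 5' vector = plus vector translated by 200 => cc(200) = 1."""
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(20_000, size=400, replace=False))
        plus = TagSet.from_arrays(["chr1"] * 400, starts, starts + 50, ["+"] * 400)
        # minus tag 5' end (half-open end) at start + 200
        minus = TagSet.from_arrays(["chr1"] * 400, starts + 150, starts + 200, ["-"] * 400)
        both = TagSet(plus.df._append(minus.df, ignore_index=True))
        prof = cross_correlation(both, {"chr1": 25_000}, max_shift=400)
        assert prof.fragment_shift == 200
        assert prof.cc[200] == pytest.approx(1.0, abs=1e-9)
        assert prof.phantom_shift == 50
        assert np.all((prof.cc >= -1 - 1e-9) & (prof.cc <= 1 + 1e-9))

    def test_small_vector_pearson_closed_form(self):
        """cc(d) equals the direct Pearson formula on the truncated slices."""
        plus_pos, minus_pos = [0, 2, 2], [1, 3, 3]
        ts = TagSet.from_arrays(
            ["chr1"] * 6,
            plus_pos + [p - 50 for p in minus_pos],
            [p + 50 for p in plus_pos] + minus_pos,
            ["+"] * 3 + ["-"] * 3)
        L = 600
        prof = cross_correlation(ts, {"chr1": L}, max_shift=60, read_length=50,
                                 exclusion_zone=(58, 59))
        plus_vec = np.bincount(plus_pos, minlength=L + 1)
        minus_vec = np.bincount(minus_pos, minlength=L + 1)
        for d in (0, 1, 2):
            x, y = plus_vec[:L + 1 - d], minus_vec[d:]
            expected = np.corrcoef(x, y)[0, 1]
            assert prof.cc[d] == pytest.approx(expected, abs=1e-12)
        # a shift beyond every minus-strand 5' end has no variance: cc = 0
        assert prof.cc[5] == 0.0

    def test_single_strand_raises(self):
        ts = TagSet.from_arrays(["chr1"] * 3, [0, 10, 20], [50, 60, 70], ["+"] * 3)
        with pytest.raises(NoSignalError):
            cross_correlation(ts, {"chr1": 1000}, max_shift=200)

    def test_fragment_shift_respects_exclusion_zone(self, good_qc):
        # session fixture computes NSC/RSC from the simulated good library;
        # the phantom artifact sits at the read length and must be excluded
        assert good_qc.metrics["NSC"] > 1.0


class TestJSD:
    def test_identical_libraries_give_zero(self):
        ts = TagSet.from_arrays(["chr1"] * 4, [0, 600, 1200, 1800],
                                [50, 650, 1250, 1850], ["+"] * 4)
        fp = jsd_fingerprint(ts, ts, {"chr1": 2500}, bin_size=500)
        assert fp.JSD == pytest.approx(0.0, abs=1e-12)

    def test_pmf_example_log2(self):
        assert jsd_from_pmfs(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == \
            pytest.approx(0.5579, abs=1e-3)

    def test_bad_bin_size(self):
        ts = TagSet.from_arrays(["chr1"], [0], [50], ["+"])
        with pytest.raises(ConfigurationError):
            jsd_fingerprint(ts, ts, {"chr1": 100}, bin_size=0)


class TestVerdicts:
    GOOD_ROW = {"NRF": 0.677, "PBC1": 0.673, "PBC2": 3.017,
                "NSC": 1.068, "RSC": 1.249, "JSD": 0.281}

    def test_full_pass_panel(self):
        report = qc_verdict(self.GOOD_ROW)
        assert all(report.verdicts.values()) and report.n_failed == 0

    def test_low_nrf_fails(self):
        metrics = dict(self.GOOD_ROW, NRF=0.435)
        report = qc_verdict(metrics)
        assert not report.verdicts["NRF"]
        assert report.n_failed == 1

    def test_boundary_values_fail_strict_comparison(self):
        thresholds = QCThresholds()
        at_bound = {"NRF": 0.5, "PBC1": 0.5, "PBC2": 1.0,
                    "NSC": 1.05, "RSC": 0.8, "JSD": 0.05}
        report = qc_verdict(at_bound, thresholds)
        assert report.n_failed == 6

    def test_infinite_pbc2_passes(self):
        report = qc_verdict(dict(self.GOOD_ROW, PBC2=float("inf")))
        assert report.verdicts["PBC2"]

    def test_missing_metric_rejected(self):
        with pytest.raises(IncompleteReportError):
            qc_verdict({"NRF": 0.9, "PBC1": 0.9})
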