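"""Window scoring, BH adjustment, narrow/island calling, consensus rule."""

import math

import numpy as np
import pytest
from scipy import stats

from equichip.errors import ValidationError
from equichip.peaks import (
    MarkConfig,
    Peak,
    WindowScores,
    bh_adjust,
    call_islands,
    call_narrow,
    combine_replicates,
    default_mark_configs,
    genome_covered_percent,
    significant,
    window_scores,
)
from equichip.readqc import TagSet


def make_peak(start, end, q, chrom="chr1", name="p", sig=None) -> Peak:
    return Peak(chrom, start, end, name, 0, ".", 1.0, q, q, -1,
                significant=bool(sig) if sig is not None else q <= 0.05)


def ws_from_p(p_values, window_size=200, lam=2.0, counts=None) -> WindowScores:
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    counts = np.asarray(counts if counts is not None else np.zeros(n))
    return WindowScores(window_size, {"chr1": n * window_size},
                        {"chr1": counts}, {"chr1": np.full(n, lam)}, {"chr1": p})


class TestWindowScores:
    def test_observed_zero_gives_p_one(self):
        ts = TagSet.from_arrays(["chr1"], [5000], [5050], ["+"])
        cfg = MarkConfig("H3K4me1", fdr_threshold=0.05)
        ws = window_scores(ts, None, {"chr1": 10_000}, cfg)
        assert ws.p["chr1"][0] == pytest.approx(1.0)  # empty first window

    def test_upper_tail_poisson_by_direct_summation(self):
        lam, obs = 2.0, 10
        direct = sum(math.exp(-lam) * lam ** k / math.factorial(k)
                     for k in range(obs, 80))
        assert stats.poisson.sf(obs - 1, lam) == pytest.approx(direct, rel=1e-10)
        assert direct == pytest.approx(4.65e-5, rel=2e-3)

    def test_window_size_from_mark_config(self):
        cfg = default_mark_configs()["H3K27me3"]
        assert cfg.window_size == 200 and cfg.gap_size == 4
        ts = TagSet.from_arrays(["chr1"] * 3, [10, 210, 410], [60, 260, 460], ["+"] * 3)
        ws = window_scores(ts, None, {"chr1": 1000}, cfg)
        assert len(ws.counts["chr1"]) == 5

    def test_input_scaled_local_lambda_floors_at_global(self):
        chip = TagSet.from_arrays(["chr1"] * 4, [0, 0, 500, 900], [50] * 2 + [550, 950],
                                  ["+"] * 4)
        inp = TagSet.from_arrays(["chr1"] * 2, [0, 0], [50, 50], ["+"] * 2)
        cfg = MarkConfig("H3K4me1", window_size=500, fragment_size=0)
        ws = window_scores(chip, inp, {"chr1": 1000}, cfg)
        lam_global = 4 * 500 / 1000
        # window 0: input count 2 scaled by depth ratio 2 -> 4 > global
        assert ws.lam["chr1"][0] == pytest.approx(4.0)
        assert ws.lam["chr1"][1] == pytest.approx(lam_global)


class TestBH:
    def test_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_null_cases(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.9, 0.02]
        q = bh_adjust(p)
        assert q[1] == q.min() and q[2] == q.max()


class TestCallNarrow:
    CFG = MarkConfig("H3K4me3", fdr_threshold=0.01)

    def test_no_candidate_windows(self):
        ws = ws_from_p([0.9] * 10)
        assert call_narrow(ws, self.CFG) == []

    def test_adjacent_windows_merge_isolated_stays(self):
        p = np.ones(10)
        p[[2, 3, 7]] = 1e-8
        ws = ws_from_p(p, counts=np.array([0, 0, 5, 9, 0, 0, 0, 6, 0, 0]))
        peaks = call_narrow(ws, self.CFG)
        assert len(peaks) == 2
        first, second = peaks
        assert (first.start, first.end) == (400, 800)
        assert (second.start, second.end) == (1400, 1600)
        # summit at midpoint of the highest-count member window
        assert first.start + first.summit == 700

    def test_significance_uses_mark_fdr(self):
        p = np.ones(20)
        p[4] = 0.004  # q = 0.08 after BH -> relaxed candidate, not significant
        ws = ws_from_p(p)
        peaks = call_narrow(ws, self.CFG)
        assert len(peaks) == 1 and not peaks[0].significant
        assert significant(peaks) == []


class TestCallIslands:
    CFG = MarkConfig("H3K27me3", "broad", 0.1, gap_size=4, genome_fraction=0.63)

    def eligibility(self, pattern, p_low=1e-12):
        p = np.where(np.array(list(pattern)) == "E", p_low, 0.99)
        return ws_from_p(p, counts=np.where(p < 0.5, 30, 0))

    def test_internal_gap_bridged(self):
        peaks = call_islands(self.eligibility("E..E......"), self.CFG)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (0, 800)

    def test_gap_beyond_limit_splits(self):
        peaks = call_islands(self.eligibility("E.....E..."), self.CFG)
        assert len(peaks) == 2

    def test_no_eligible_windows(self):
        assert call_islands(self.eligibility("." * 10), self.CFG) == []

    def test_gap_zero_equals_run_merge_oracle(self):
        rng = np.random.default_rng(5)
        cfg = MarkConfig("H3K27me3", "broad", 0.1, gap_size=0, relaxed_q=1.0)
        for _ in range(25):
            eligible = rng.random(40) < 0.3
            ws = self.eligibility("".join("E" if e else "." for e in eligible))
            islands = call_islands(ws, cfg)
            spans = [(p.start // 200, p.end // 200) for p in islands]
            # oracle: simple linear scan of maximal eligible runs
            oracle, run = [], None
            for i, e in enumerate(eligible):
                if e and run is None:
                    run = i
                if not e and run is not None:
                    oracle.append((run, i))
                    run = None
            if run is not None:
                oracle.append((run, len(eligible)))
            assert spans == oracle


class TestCombineReplicates:
    CFG = MarkConfig("H3K4me1", fdr_threshold=0.05)

    def test_union_span_when_one_member_significant(self):
        r1 = [make_peak(100, 300, 0.001)]
        r2 = [make_peak(250, 400, 0.3)]
        cps = combine_replicates(r1, r2, self.CFG)
        assert len(cps) == 1
        assert (cps.peaks[0].start, cps.peaks[0].end) == (100, 400)

    def test_no_significant_member_discarded(self):
        cps = combine_replicates([make_peak(100, 300, 0.2)],
                                 [make_peak(250, 400, 0.2)], self.CFG)
        assert len(cps) == 0

    def test_must_appear_in_both_replicates(self):
        cps = combine_replicates([make_peak(100, 300, 1e-10)],
                                 [make_peak(5000, 5200, 1e-10)], self.CFG)
        assert len(cps) == 0

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            r1 = [make_peak(int(s), int(s + rng.integers(50, 400)),
                            float(rng.random()))
                  for s in rng.integers(0, 20_000, size=8)]
            r2 = [make_peak(int(s), int(s + rng.integers(50, 400)),
                            float(rng.random()))
                  for s in rng.integers(0, 20_000, size=8)]
            a = combine_replicates(r1, r2, self.CFG)
            b = combine_replicates(r2, r1, self.CFG)
            assert [(p.start, p.end) for p in a.peaks] == \
                [(p.start, p.end) for p in b.peaks]

    def test_chained_overlap_emits_single_component(self):
        r1 = [make_peak(0, 150, 0.001), make_peak(220, 350, 0.9)]
        r2 = [make_peak(100, 250, 0.9)]
        cps = combine_replicates(r1, r2, self.CFG)
        assert len(cps) == 1
        assert (cps.peaks[0].start, cps.peaks[0].end) == (0, 350)

    def test_disjoint_chromosome_namespaces_rejected(self):
        with pytest.raises(ValidationError):
            combine_replicates([make_peak(0, 100, 0.01, chrom="chr1")],
                               [make_peak(0, 100, 0.01, chrom="chrX")], self.CFG)

    def test_consensus_can_exceed_smaller_replicate_significant_count(self):
        """Replicate-level sub-significant enrichment still combines, so a
        consensus set can outnumber the smaller replicate's significant calls."""
        r1 = [make_peak(i * 1000, i * 1000 + 300, 0.001) for i in range(5)]
        r2 = [make_peak(i * 1000 + 100, i * 1000 + 400, 0.4) for i in range(5)]
        cps = combine_replicates(r1, r2, self.CFG)
        n_sig_r2 = len(significant(r2))
        assert n_sig_r2 == 0
        assert len(cps) == 5 > min(len(significant(r1)), n_sig_r2)


class TestGenomeCovered:
    SIZES = {"chr1": 10_000}

    def test_no_peaks(self):
        assert genome_covered_percent([], self.SIZES) == 0.0

    def test_overlapping_union(self):
        peaks = [make_peak(0, 500, 0.01), make_peak(250, 1000, 0.01)]
        assert genome_covered_percent(peaks, self.SIZES) == pytest.approx(10.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            genome_covered_percent([make_peak(9000, 11_000, 0.01)], self.SIZES)


def test_default_mark_configs_match_study_parameters():
    cfgs = default_mark_configs()
    assert [cfgs[m].fdr_threshold for m in
            ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")] == [0.05, 0.01, 0.01, 0.1]
    assert all(c.fragment_size == 200 for c in cfgs.values())
    broad = cfgs["H3K27me3"]
    assert broad.peak_type == "broad"
    assert (broad.window_size, broad.gap_size, broad.genome_fraction) == (200, 4, 0.63)
    assert broad.effective_genome_size == 2_409_143_234
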