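"""Background-normalized binding bias: nfc, scaling, classification,
summit profiles."""

import numpy as np
import pytest

from chipcis.cobinding import (
    A_BIASED,
    B_BIASED,
    UNBIASED,
    CountsUnavailableError,
    attach_counts_from_coverage,
    build_joint_sites,
    normalized_fold_change,
    rescale_0_100,
    summarize_bias,
    summit_profile,
)
from chipcis.intervals import GenomicInterval, ScoredPeak
from chipcis.synthetic import CobindSimConfig, simulate_cobinding


def make_peak(chrom="chr1", start=100, end=400, read=50.0, bg=10.0):
    return ScoredPeak(
        interval=GenomicInterval(chrom, start, end),
        summit=(start + end) // 2,
        fold_change=10.0,
        neg_log10_q=50.0,
        read_count=read,
        background_count=bg,
    )


class TestNormalizedFoldChange:
    def test_stated_arithmetic(self):
        assert normalized_fold_change(make_peak(read=50, bg=10)) == pytest.approx(51 / 11)

    def test_degenerate_site_neutral(self):
        assert normalized_fold_change(make_peak(read=0, bg=0)) == 1.0

    def test_missing_counts_signalled(self):
        p = ScoredPeak(GenomicInterval("chr1", 0, 100), 50, 10.0, 50.0)
        with pytest.raises(CountsUnavailableError, match="counts unavailable"):
            normalized_fold_change(p)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        reads = rng.integers(0, 500, 500)
        bgs = rng.integers(0, 100, 500)
        for r, b in zip(reads, bgs):
            assert normalized_fold_change(make_peak(read=r, bg=b)) == (r + 1) / (b + 1)


class TestRescale:
    def test_equally_spaced(self):
        assert rescale_0_100([2, 7, 12]) == [0.0, 50.0, 100.0]

    def test_ties_share_position(self):
        assert rescale_0_100([5, 5, 10]) == [0.0, 0.0, 100.0]

    def test_degenerate_and_too_few(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescale_0_100([3, 3, 3])
        with pytest.raises(ValueError):
            rescale_0_100([3])

    def test_monotone_endpoints_formula(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 50, 200).tolist()
        scaled = rescale_0_100(vals)
        lo, hi = min(vals), max(vals)
        assert min(scaled) == 0.0 and max(scaled) == 100.0
        for v, s in zip(vals, scaled):
            assert s == pytest.approx(100 * (v - lo) / (hi - lo))
        order = np.argsort(vals)
        assert np.all(np.diff(np.asarray(scaled)[order]) >= 0)


class TestBuildJointSites:
    def _pair(self, ra, rb):
        a = [make_peak(read=ra, bg=9.0), make_peak(start=5000, end=5300, read=40, bg=9)]
        b = [make_peak(read=rb, bg=9.0), make_peak(start=5100, end=5400, read=80, bg=9)]
        return build_joint_sites(a, b)

    def test_two_fold_rule_strict(self):
        # nfc ratio 21/10 = 2.1 > 2 -> B-biased; 19/10 = 1.9 <= 2 -> unbiased
        b_site = self._pair(ra=99.0, rb=209.0)[0]  # nfc 10 vs 21
        assert (b_site.nfcA, b_site.nfcB) == (10.0, 21.0)
        assert b_site.bias == B_BIASED
        un = self._pair(ra=99.0, rb=189.0)[0]  # nfc 10 vs 19
        assert un.bias == UNBIASED

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_joint_sites([], [], bias_threshold=1.0)

    def test_merged_contains_both_and_scaled_range(self):
        sim = simulate_cobinding(CobindSimConfig(n_joint=50, n_biased=30, seed=4))
        sites = build_joint_sites(sim.peaksA, sim.peaksB)
        for s in sites:
            assert s.merged.start <= s.peakA.interval.start
            assert s.merged.end >= s.peakB.interval.end
            assert 0 <= s.scaledA <= 100 and 0 <= s.scaledB <= 100
            assert s.bias in (A_BIASED, B_BIASED, UNBIASED)

    def test_scale_invariance_of_bias(self):
        """Multiplying one factor's read AND background counts by a constant
        (library depth) leaves nfc ratios, hence labels, unchanged."""
        rng = np.random.default_rng(14)
        a, b = [], []
        for k in range(60):
            start = 1000 * (k + 1)
            a.append(make_peak(start=start, end=start + 300,
                               read=float(rng.integers(10, 300)),
                               bg=float(rng.integers(5, 50))))
            b.append(make_peak(start=start + 40, end=start + 340,
                               read=float(rng.integers(10, 300)),
                               bg=float(rng.integers(5, 50))))
        base = build_joint_sites(a, b, pseudocount=0.0)
        scaled_a = [p.with_counts(p.read_count * 7, p.background_count * 7) for p in a]
        scaled = build_joint_sites(scaled_a, b, pseudocount=0.0)
        assert [s.bias for s in base] == [s.bias for s in scaled]

    def test_multi_overlap_keeps_largest_overlap(self):
        a = [make_peak(start=100, end=500)]
        b = [make_peak(start=80, end=150, read=99),   # 50 bp overlap
             make_peak(start=300, end=600, read=10)]  # 200 bp overlap
        sites = build_joint_sites(a, b)
        assert len(sites) == 1
        assert sites[0].peakB.interval.start == 300

    def test_planted_labels_recovered(self):
        """Generator bookkeeping oracle: recovered labels match the plant at
        every joint site whose realized nfc ratio falls on the planted side
        of the 2-fold threshold."""
        sim = simulate_cobinding(CobindSimConfig(n_joint=300, n_biased=180,
                                                 frac_A_of_biased=0.6, seed=21))
        sites = build_joint_sites(sim.peaksA, sim.peaksB)
        joint_truth = sim.truth[sim.truth.kind == "joint"].reset_index(drop=True)
        by_start = {}
        for _, row in joint_truth.iterrows():
            by_start[(row.chrom, row.start)] = row.planted_bias
        checked = 0
        for s in sites:
            key = (s.peakA.chrom, s.peakA.interval.start)
            planted = by_start.get(key)
            assert planted is not None
            ratio = s.nfcA / s.nfcB
            if planted == "A" and ratio > 2:
                assert s.bias == A_BIASED
                checked += 1
            elif planted == "B" and 1 / ratio > 2:
                assert s.bias == B_BIASED
                checked += 1
        assert checked > 100  # the plant is strong enough to be seen


class TestSummarizeBias:
    def test_printed_worked_example(self):
        """358 A-biased + 225 B-biased sites -> 61% / 39% split."""
        sites = []
        a = make_peak(read=500, bg=10)
        b = make_peak(read=20, bg=10)
        for k in range(358):
            sites.append(_joint(a, b, A_BIASED))
        for k in range(225):
            sites.append(_joint(a, b, B_BIASED))
        s = summarize_bias(sites)
        assert (s.n_biased, s.n_A, s.n_B) == (583, 358, 225)
        assert (s.pct_A, s.pct_B) == (61, 39)
        assert s.frac_A + s.frac_B == pytest.approx(1.0)

    def test_empty_fractions_na(self):
        s = summarize_bias([])
        assert s.n_joint == 0 and s.frac_A is None and s.pct_B is None

    def test_counts_equal_tally_oracle(self):
        rng = np.random.default_rng(2)
        labels = rng.choice([A_BIASED, B_BIASED, UNBIASED], 400)
        a = make_peak()
        sites = [_joint(a, a, lab) for lab in labels]
        s = summarize_bias(sites)
        tally = {lab: int((labels == lab).sum()) for lab in set(labels)}
        assert s.n_A == tally.get(A_BIASED, 0)
        assert s.n_B == tally.get(B_BIASED, 0)
        assert s.n_joint == len(labels)
        assert s.n_A + s.n_B == s.n_biased <= s.n_joint


def _joint(a, b, bias):
    from chipcis.cobinding import JointSite

    return JointSite(peakA=a, peakB=b, merged=a.interval.span_with(b.interval),
                     nfcA=1.0, nfcB=1.0, scaledA=0.0, scaledB=0.0, bias=bias)


class TestSummitProfile:
    def test_flat_coverage(self):
        cov = {"t": {"chr1": np.full(5000, 3.0)}}
        prof = summit_profile([("chr1", 2500)], cov, halfwidth=100)
        assert prof.mean_signal["t"].shape == (201,)
        assert np.allclose(prof.mean_signal["t"], 3.0)

    def test_delta_at_summit(self):
        arr = np.zeros(5000)
        arr[[1000, 3000]] = 1.0
        prof = summit_profile([("chr1", 1000), ("chr1", 3000)],
                              {"t": {"chr1": arr}}, halfwidth=50)
        expect = np.zeros(101)
        expect[50] = 1.0
        assert np.array_equal(prof.mean_signal["t"], expect)

    def test_empty_summits_rejected(self):
        with pytest.raises(ValueError):
            summit_profile([], {"t": {"chr1": np.zeros(10)}})

    def test_matches_per_offset_loop_oracle(self):
        rng = np.random.default_rng(13)
        chrom_len = 3000
        arr = np.zeros(chrom_len)
        hot = rng.choice(chrom_len, 200, replace=False)
        arr[hot] = rng.uniform(0, 5, 200)
        summits = [("chr1", int(p)) for p in rng.integers(0, chrom_len, 50)]
        hw = 120
        prof = summit_profile(summits, {"t": {"chr1": arr}}, halfwidth=hw)
        # independent per-offset loop, truncating at chromosome edges
        for idx, off in enumerate(range(-hw, hw + 1)):
            vals = [arr[p + off] for _, p in summits if 0 <= p + off < chrom_len]
            expect = np.mean(vals) if vals else 0.0
            assert prof.mean_signal["t"][idx] == pytest.approx(expect)


class TestAttachCountsFromCoverage:
    def test_uniform_coverage_gives_equal_counts(self):
        cov = {"chr1": np.full(10_000, 2.0)}
        p = ScoredPeak(GenomicInterval("chr1", 4000, 4500), 4200, 10.0, 50.0)
        (out,) = attach_counts_from_coverage([p], cov)
        assert out.read_count == pytest.approx(1000.0)
        assert out.background_count == pytest.approx(1000.0)

    def test_truncated_flank_rescaled(self):
        cov = {"chr1": np.full(1000, 1.0)}
        p = ScoredPeak(GenomicInterval("chr1", 100, 400), 200, 10.0, 50.0)
        (out,) = attach_counts_from_coverage([p], cov)
        # left flank truncated to 100 bp, right full: 400 bp of flank at
        # coverage 1 rescaled to the 300 bp peak length
        assert out.background_count == pytest.approx(400 * 300 / 400)
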