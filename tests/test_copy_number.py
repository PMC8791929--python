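"""Purity correction, CN classification, deletion CCF and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tp53hit.copy_number import (
    CopyNumberError,
    GenomicInterval,
    InvalidPurityError,
    MissingCoverageError,
    ProbeTrack,
    Segment,
    TP53_LOCUS,
    classify_cn,
    deletion_ccf,
    gene_level_call,
    logratio_to_tumor_cn,
    segment_probes,
    tumor_cn_to_logratio,
)


class TestLogratioToTumorCN:
    @pytest.mark.parametrize(
        "log2_ratio, purity, expected",
        [
            (0.0, 1.0, 2.0),  # diploid identity
            # forward oracle: tumor CN 1 at purity 0.5 mixes to (0.5*1+0.5*2)=1.5
            (np.log2(1.5 / 2.0), 0.5, 1.0),
            (np.log2(0.75), 1.0, 1.5),
        ],
    )
    def test_worked_examples(self, log2_ratio, purity, expected):
        assert logratio_to_tumor_cn(log2_ratio, purity) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("purity", [0.0, -0.2, 1.5])
    def test_invalid_purity(self, purity):
        with pytest.raises(InvalidPurityError):
            logratio_to_tumor_cn(0.0, purity)

    @given(
        cn=st.floats(0.0, 4.0),
        purity=st.floats(0.3, 1.0),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_round_trip(self, cn, purity):
        """Noise-free forward-then-invert recovers the tumor CN exactly."""
        lr = tumor_cn_to_logratio(cn, purity)
        assert logratio_to_tumor_cn(lr, purity) == pytest.approx(cn, abs=1e-9)

    def test_strictly_increasing_in_logratio(self):
        grid = np.linspace(-3, 2, 200)
        cns = logratio_to_tumor_cn(grid, 0.6)
        positive = cns[cns > 0]  # clamp at 0 flattens the left tail
        assert np.all(np.diff(positive) > 0)


class TestClassifyCN:
    @pytest.mark.parametrize(
        "cn, expected",
        [
            (2.0, "neutral"),
            (0.5, "homozygous_loss"),
            (1.5, "single_loss"),
            # boundary conventions
            (0.6, "homozygous_loss"),
            (0.6 + 1e-9, "single_loss"),
            (1.9, "neutral"),
            (1.9 - 1e-9, "single_loss"),
            (2.1, "neutral"),
            (2.1 + 1e-9, "single_gain"),
            (3.4, "multi_gain"),
            (3.4 - 1e-9, "single_gain"),
            (0.0, "homozygous_loss"),
        ],
    )
    def test_thresholds(self, cn, expected):
        assert classify_cn(cn) == expected

    def test_negative_rejected(self):
        with pytest.raises(CopyNumberError):
            classify_cn(-0.1)


class TestDeletionCCF:
    @pytest.mark.parametrize(
        "cn, expected",
        [(1.9, 10.0), (1.0, 100.0), (2.0, 0.0), (2.5, 0.0), (0.3, 100.0)],
    )
    def test_hemizygous_model(self, cn, expected):
        assert deletion_ccf(cn) == pytest.approx(expected)

    def test_non_increasing_in_cn(self):
        grid = np.linspace(0, 4, 400)
        ccfs = np.array([deletion_ccf(c) for c in grid])
        assert np.all(np.diff(ccfs) <= 0)


class TestGeneLevelCall:
    def _one_segment(self, tumor_cn, purity):
        lr = tumor_cn_to_logratio(tumor_cn, purity)
        return [Segment("chr17", TP53_LOCUS.start - 10_000, TP53_LOCUS.end + 10_000, lr, 50)]

    def test_neutral_not_deleted(self):
        call = gene_level_call(self._one_segment(2.0, 0.8), 0.8, sample_id="s1")
        assert call.cn_class == "neutral"
        assert not call.is_deleted and not call.is_homdel

    def test_ccf_15_deleted_at_cutoff_10(self):
        call = gene_level_call(self._one_segment(1.85, 0.7), 0.7)
        assert call.deletion_ccf == pytest.approx(15.0, abs=1e-9)
        assert call.is_deleted

    def test_ccf_5_below_cutoff(self):
        call = gene_level_call(self._one_segment(1.95, 0.7), 0.7)
        assert call.deletion_ccf == pytest.approx(5.0, abs=1e-9)
        assert not call.is_deleted

    def test_homdel_segment_dominates_weighted_mean(self):
        """A focal biallelic loss is not averaged away by a neutral flank."""
        mid = (TP53_LOCUS.start + TP53_LOCUS.end) // 2
        segs = [
            Segment("chr17", TP53_LOCUS.start - 50_000, mid,
                    tumor_cn_to_logratio(2.0, 1.0), 40),
            Segment("chr17", mid + 1, TP53_LOCUS.end + 50_000,
                    tumor_cn_to_logratio(0.4, 1.0), 40),
        ]
        call = gene_level_call(segs, 1.0)
        assert call.cn_class == "homozygous_loss"
        assert call.is_homdel and call.is_deleted
        assert call.tumor_cn == pytest.approx(0.4, abs=1e-9)

    def test_weighted_mean_over_partial_overlaps(self):
        # left half deleted (cn 1), right half neutral -> mean log-ratio mix
        mid = (TP53_LOCUS.start + TP53_LOCUS.end) // 2
        segs = [
            Segment("chr17", TP53_LOCUS.start, mid, tumor_cn_to_logratio(1.0, 1.0), 40),
            Segment("chr17", mid + 1, TP53_LOCUS.end, tumor_cn_to_logratio(2.0, 1.0), 40),
        ]
        call = gene_level_call(segs, 1.0)
        expected_lr = (np.log2(0.5) + 0.0) / 2  # equal-length weights
        assert call.tumor_cn == pytest.approx(
            logratio_to_tumor_cn(expected_lr, 1.0), rel=1e-6
        )

    def test_no_overlap_raises(self):
        segs = [Segment("chr1", 1, 1000, 0.0, 10)]
        with pytest.raises(MissingCoverageError):
            gene_level_call(segs, 0.9)

    def test_is_homdel_implies_is_deleted(self, fixture_analysis):
        cn_calls, _, _ = fixture_analysis
        for call in cn_calls:
            assert not call.is_homdel or call.is_deleted
            assert 0.0 <= call.deletion_ccf <= 100.0


class TestSegmentProbes:
    def test_constant_track_single_segment(self):
        track = ProbeTrack("chr17", np.arange(200) * 1000 + 1, np.zeros(200))
        segs = segment_probes(track, alpha=1e-7)
        assert len(segs) == 1
        assert segs[0].n_probes == 200

    def test_known_changepoint_recovered(self, rng):
        """100 + 100 probes with a -1 jump: breakpoint within +-3 probes."""
        lr = np.concatenate([np.zeros(100), -np.ones(100)])
        lr = lr + rng.normal(0, 0.05, 200)
        track = ProbeTrack("chr17", np.arange(200) * 1000 + 1, lr)
        segs = segment_probes(track, alpha=1e-7)
        assert len(segs) == 2
        breakpoint_probe = segs[0].n_probes
        assert abs(breakpoint_probe - 100) <= 3

    def test_alpha_limits(self):
        # alpha = 0 never splits, even a blatant jump
        lr = np.concatenate([np.zeros(5), np.ones(5)])
        track = ProbeTrack("chr17", np.arange(10) + 1, lr)
        assert len(segment_probes(track, alpha=0.0)) == 1
        # alpha = 1 permits splitting wherever any contrast exists
        assert len(segment_probes(track, alpha=1.0)) > 1
        two = ProbeTrack("chr17", np.array([1, 2]), np.array([0.0, 0.3]))
        assert len(segment_probes(two, alpha=1.0)) == 2
        assert len(segment_probes(two, alpha=1e-7)) == 1

    def test_partition_property(self, rng):
        lr = rng.normal(0, 0.2, 150)
        lr[60:] -= 1.2
        track = ProbeTrack("chr17", np.sort(rng.choice(10**6, 150, replace=False)), lr)
        segs = segment_probes(track, alpha=1e-4)
        assert sum(s.n_probes for s in segs) == 150
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start

    def test_degenerate_input(self):
        with pytest.raises(CopyNumberError):
            segment_probes(ProbeTrack("chr17", np.array([5]), np.array([0.0])))


class TestCCFRecovery:
    def test_noisy_probe_recovery_within_5_points(self):
        """Estimated deletion CCF within 5 points of truth in >=95% of 500
        noisy replicates (noise sd 0.1, 100 probes over the locus,
        purity 0.4-1.0)."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            purity = rng.uniform(0.4, 1.0)
            true_ccf = rng.uniform(10, 100)
            cn = 2 - true_ccf / 100
            pos = np.linspace(TP53_LOCUS.start, TP53_LOCUS.end, 100).astype(int)
            lr = tumor_cn_to_logratio(cn, purity) + rng.normal(0, 0.1, 100)
            segs = segment_probes(ProbeTrack("chr17", pos, lr), alpha=1e-7)
            call = gene_level_call(segs, purity)
            hits += abs(call.deletion_ccf - true_ccf) < 5
        assert hits / n_rep >= 0.95
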