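"""Sliding windows, density correlation, contamination flags, contiguity."""

import numpy as np
import pytest

from wavyselect.genome_qc import (
    GenomicWindow,
    contiguity_stats,
    count_features_in_windows,
    density_correlation,
    flag_contamination_windows,
    make_windows,
)
from wavyselect.io_formats import FeatureRecord


def windows_with_counts(pairs):
    return [
        GenomicWindow("c", i * 100, i * 100 + 100, g, r)
        for i, (g, r) in enumerate(pairs)
    ]


class TestMakeWindows:
    def test_default_sliding_windows(self):
        wins = make_windows({"chr1": 2_500_000})
        assert len(wins) == 16
        assert (wins[0].start, wins[0].end) == (0, 1_000_000)
        assert (wins[-1].start, wins[-1].end) == (1_500_000, 2_500_000)

    def test_short_chromosome_single_window(self):
        (w,) = make_windows({"chr1": 800_000})
        assert (w.start, w.end) == (0, 800_000)

    def test_step_equals_width_tiles(self):
        wins = make_windows({"c": 1_000_000}, width=100_000, step=100_000)
        assert len(wins) == 10
        starts = [w.start for w in wins]
        ends = [w.end for w in wins]
        assert starts[1:] == ends[:-1]

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 0})


class TestCountFeatures:
    def test_overlap_counts(self):
        wins = make_windows({"c": 1_000_000})
        counted = count_features_in_windows(
            wins, [FeatureRecord("c", 100, 200, "gene")]
        )
        assert counted[0].gene_count == 1

    def test_feature_counted_in_every_overlapping_window(self):
        wins = make_windows({"c": 2_000_000})  # starts 0..1M step 100k
        feat = FeatureRecord("c", 999_990, 1_000_010, "repeat")
        counted = count_features_in_windows(wins, [feat])
        # feature straddles 1 Mb: overlaps every window
        assert all(w.repeat_count == 1 for w in counted)

    def test_hand_enumerated_fixture(self):
        wins = make_windows({"c": 2_500_000}, width=1_000_000, step=500_000)
        feats = [
            FeatureRecord("c", 10, 20, "gene"),          # windows starting <= 10
            FeatureRecord("c", 1_200_000, 1_200_100, "gene"),
            FeatureRecord("c", 2_400_000, 2_400_010, "gene"),
            FeatureRecord("c", 600_000, 600_050, "repeat"),
            FeatureRecord("c", 1_499_999, 1_500_001, "repeat"),
        ]
        counted = count_features_in_windows(wins, feats)
        # windows start at 0, 0.5M, 1.0M, 1.5M; the 1.2M gene falls in two
        # overlapping windows, the boundary-straddling repeat in three
        assert [w.gene_count for w in counted] == [1, 1, 1, 1]
        assert [w.repeat_count for w in counted] == [1, 2, 1, 1]

    def test_unknown_chromosome_warns_and_skips(self):
        wins = make_windows({"c": 1_000_000})
        with pytest.warns(UserWarning, match="skipped"):
            counted = count_features_in_windows(
                wins, [FeatureRecord("other", 0, 10, "gene")]
            )
        assert counted[0].gene_count == 0

    def test_tiling_conserves_point_features(self, rng):
        # step == width, 1 bp features on covered territory
        wins = make_windows({"c": 1_000_000}, width=50_000, step=50_000)
        feats = [
            FeatureRecord("c", int(s), int(s) + 1, "gene")
            for s in rng.integers(0, 1_000_000, size=500)
        ]
        counted = count_features_in_windows(wins, feats)
        assert sum(w.gene_count for w in counted) == 500


class TestDensityCorrelation:
    def test_identical_tracks_perfectly_correlated(self):
        wins = windows_with_counts([(1, 1), (5, 5), (9, 9), (2, 2)])
        assert density_correlation(wins) == pytest.approx(1.0)

    def test_affine_inverse_tracks_anticorrelated(self):
        wins = windows_with_counts([(1, 9), (5, 5), (9, 1), (2, 8)])
        assert density_correlation(wins) == pytest.approx(-1.0)

    def test_constant_track_undefined(self):
        wins = windows_with_counts([(3, 1), (3, 5), (3, 9)])
        with pytest.raises(ValueError, match="undefined"):
            density_correlation(wins)


class TestFlagContamination:
    def test_uniform_counts_nothing_flagged(self):
        wins = windows_with_counts([(10, 100)] * 12)
        assert flag_contamination_windows(wins).flagged == ()

    def test_gene_dense_repeat_poor_window_flagged(self):
        pairs = [(10, 100)] * 11 + [(100, 20)]
        summary = flag_contamination_windows(windows_with_counts(pairs))
        assert len(summary.flagged) == 1
        assert summary.flagged[0].gene_count == 100

    def test_gene_dense_but_repeat_rich_not_flagged(self):
        pairs = [(10, 100)] * 11 + [(100, 90)]
        assert flag_contamination_windows(windows_with_counts(pairs)).flagged == ()

    def test_zero_repeat_median_vacuous_repeat_condition(self):
        pairs = [(10, 0)] * 11 + [(100, 0)]
        summary = flag_contamination_windows(windows_with_counts(pairs))
        assert len(summary.flagged) == 1

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            flag_contamination_windows(windows_with_counts([(1, 1)] * 5))


def planted_genome_features(rng, chrom_len, plant_start):
    """Homogeneous gene/repeat background with a 100 kb gene-dense,
    repeat-free block planted at plant_start."""
    feats = []
    for track, per_mb, flen in (("gene", 60, 500), ("repeat", 400, 300)):
        n = rng.poisson(per_mb * chrom_len / 1e6)
        for s in rng.integers(0, chrom_len - flen, size=n):
            feats.append(FeatureRecord("chr1", int(s), int(s) + flen, track))
    for s in rng.integers(plant_start, plant_start + 100_000 - 200, size=300):
        feats.append(FeatureRecord("chr1", int(s), int(s) + 200, "gene"))
    return [
        f
        for f in feats
        if not (
            f.track == "repeat"
            and plant_start - 300 <= f.start < plant_start + 100_000
        )
    ]


class TestPlantedContamination:
    CHROM = 10_000_000

    def test_planted_block_flagged_nowhere_else(self):
        rng = np.random.default_rng(3)
        plant = 2_340_000
        wins = make_windows({"chr1": self.CHROM}, width=100_000, step=100_000)
        counted = count_features_in_windows(
            wins, planted_genome_features(rng, self.CHROM, plant)
        )
        summary = flag_contamination_windows(counted)
        assert any(
            w.start < plant + 100_000 and w.end > plant for w in summary.flagged
        )
        assert all(
            w.start < plant + 100_000 and w.end > plant for w in summary.flagged
        )

    def test_homogeneous_simulations_rarely_flag(self):
        rng = np.random.default_rng(0)
        wins = make_windows({"chr1": self.CHROM}, width=100_000, step=100_000)
        flagged = total = 0
        for _ in range(10):
            feats = []
            for track, per_mb, flen in (("gene", 60, 500), ("repeat", 400, 300)):
                n = rng.poisson(per_mb * self.CHROM / 1e6)
                for s in rng.integers(0, self.CHROM - flen, size=n):
                    feats.append(
                        FeatureRecord("chr1", int(s), int(s) + flen, track)
                    )
            counted = count_features_in_windows(wins, feats)
            flagged += len(flag_contamination_windows(counted).flagged)
            total += len(wins)
        assert flagged / total <= 0.01


def brute_force_contiguity(lengths):
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    out = {}
    for frac, tag in ((0.5, "50"), (0.9, "90")):
        acc = 0
        for rank, ln in enumerate(ordered, start=1):
            acc += ln
            if acc >= frac * total:
                out["N" + tag], out["L" + tag] = ln, rank
                break
    return out


class TestContiguityStats:
    def test_worked_example(self):
        s = contiguity_stats([100, 50, 50])
        assert (s.N50, s.L50, s.N90, s.L90) == (100, 1, 50, 3)

    def test_single_sequence(self):
        s = contiguity_stats([12345])
        assert (s.N50, s.L50) == (12345, 1)

    def test_ten_equal_sequences(self):
        s = contiguity_stats([10] * 10)
        assert (s.N50, s.L50) == (10, 5)

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 60)))
            s = contiguity_stats(lengths)
            ref = brute_force_contiguity(lengths.tolist())
            assert (s.N50, s.L50, s.N90, s.L90) == (
                ref["N50"], ref["L50"], ref["N90"], ref["L90"],
            )
            assert s.N90 <= s.N50 and s.L50 <= s.L90 <= s.n_seqs

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contiguity_stats([])
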