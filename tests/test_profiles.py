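"""Strand-shifted occupancy scoring and metagene profiles."""

from __future__ import annotations

import numpy as np
import pytest

from polyanuc import (TagCollection, aggregate_profile, build_profile_matrix,
                      occupancy_score, score_track)
from polyanuc.profiles import moving_average

from conftest import make_site, mirror_site, mirror_tags, naive_occupancy, random_tags


class TestOccupancyScore:
    def test_empty_library_scores_zero(self):
        tags = TagCollection.from_positions()
        assert occupancy_score(tags, "chr1", 500, 80) == 0.0

    def test_one_tag_each_side(self):
        tags = TagCollection.from_positions({"chr1": [460]}, {"chr1": [540]})
        assert occupancy_score(tags, "chr1", 500, 80) == 1.0

    def test_window_half_openness(self):
        # + tag exactly at the locus is outside [pos-shift, pos);
        # - tag exactly at the locus is inside [pos, pos+shift)
        tags = TagCollection.from_positions({"chr1": [500]}, {"chr1": [500]})
        assert occupancy_score(tags, "chr1", 500, 80) == 0.5

    def test_matches_bruteforce_on_random_tags(self, rng):
        tags = random_tags(rng, chrom_len=10_000, n=500)
        plus, minus = tags.arrays("chr1")
        for pos in rng.integers(0, 10_000, 50):
            assert occupancy_score(tags, "chr1", int(pos), 80) == naive_occupancy(
                plus, minus, int(pos), 80)

    def test_per_million_scaling(self):
        tags = TagCollection.from_positions({"chr1": [460]}, {"chr1": [540]})
        assert occupancy_score(tags, "chr1", 500, 80, per_million=True) == 1.0 * 1e6 / 2


class TestScoreTrack:
    def test_equals_per_locus_scoring(self, rng):
        tags = random_tags(rng, chrom_len=5_000, n=300)
        track = score_track(tags, "chr1", 100, 4900, shift=80)
        check = rng.choice(len(track.scores), 100)
        for i in check:
            pos = int(track.positions[i])
            assert track.scores[i] == occupancy_score(tags, "chr1", pos, 80)

    def test_two_point_track_at_span_equal_step(self, rng):
        tags = random_tags(rng)
        track = score_track(tags, "chr1", 1000, 1100, shift=80, step=100)
        assert len(track.scores) == 2

    def test_uniform_density_expectation(self, rng):
        # Poisson tags at rate lam per base per strand: E[score] = lam * shift
        lam, length, shift = 0.2, 200_000, 80
        plus = np.sort(rng.integers(0, length, rng.poisson(lam * length)))
        minus = np.sort(rng.integers(0, length, rng.poisson(lam * length)))
        tags = TagCollection.from_positions({"c": plus}, {"c": minus})
        track = score_track(tags, "c", 1000, length - 1000, shift=shift)
        expected = lam * shift
        se = np.sqrt(lam * shift / 2 / len(track.scores))  # generous normal bound
        assert abs(track.scores.mean() - expected) < 6 * se + 0.05 * expected

    def test_region_smaller_than_step_rejected(self, rng):
        with pytest.raises(ValueError):
            score_track(random_tags(rng), "chr1", 100, 105, shift=80)

    def test_monotone_in_tags(self, rng):
        base = random_tags(rng, n=200)
        extra_plus = np.sort(np.concatenate([base.plus["chr1"],
                                             rng.integers(0, 10_000, 100)]))
        more = TagCollection.from_positions({"chr1": extra_plus},
                                            {"chr1": base.minus["chr1"]})
        t0 = score_track(base, "chr1", 0, 10_000, shift=80).scores
        t1 = score_track(more, "chr1", 0, 10_000, shift=80).scores
        assert np.all(t1 >= t0)


class TestProfileMatrix:
    def spike_tags(self, center: int) -> TagCollection:
        # 10 dyads exactly at `center`: + tags at center-73, - at center+73
        return TagCollection.from_positions(
            {"chr1": np.full(10, center - 73)}, {"chr1": np.full(10, center + 73)})

    def test_spike_downstream_peaks_at_its_offset(self):
        site = make_site(position=5000)
        tags = self.spike_tags(5150)
        m = build_profile_matrix(tags, [site], shift=80)
        assert m.offsets[np.argmax(m.values[0])] == 150

    def test_minus_strand_orientation_correction(self):
        # transcription-downstream of a - strand site is genomically upstream
        site = make_site(strand="-", position=5000)
        tags = self.spike_tags(5000 - 150)
        m = build_profile_matrix(tags, [site], shift=80)
        assert m.offsets[np.argmax(m.values[0])] == 150

    def test_rows_equal_score_track(self, rng):
        tags = random_tags(rng, chrom_len=50_000, n=2000)
        sites = [make_site(f"s{i}", position=int(p),
                           strand="+" if i % 2 else "-")
                 for i, p in enumerate(rng.integers(2000, 48_000, 20))]
        m = build_profile_matrix(tags, sites, shift=80)
        for i, site in enumerate(sites):
            track = score_track(tags, "chr1", site.position - 1000,
                                site.position + 1000, shift=80)
            row = track.scores if site.strand == "+" else track.scores[::-1]
            np.testing.assert_array_equal(m.values[i], row)

    def test_out_of_bounds_offsets_are_nan(self, rng):
        tags = random_tags(rng, chrom_len=3000)
        site = make_site(position=400)
        m = build_profile_matrix(tags, [site], shift=80,
                                 chrom_sizes={"chr1": 3000})
        assert np.isnan(m.values[0][m.offsets < -400]).all()
        assert not np.isnan(m.values[0][m.offsets >= -400]).any()

    def test_empty_sites_rejected(self, rng):
        with pytest.raises(ValueError):
            build_profile_matrix(random_tags(rng), [], shift=80)

    def test_translation_invariance(self, rng):
        shift_by = 12_345
        tags = random_tags(rng, chrom_len=30_000, n=800)
        moved = TagCollection.from_positions(
            {"chr1": tags.plus["chr1"] + shift_by},
            {"chr1": tags.minus["chr1"] + shift_by})
        sites = [make_site(f"s{i}", position=int(p))
                 for i, p in enumerate(rng.integers(2000, 28_000, 10))]
        moved_sites = [make_site(s.site_id, position=s.position + shift_by)
                       for s in sites]
        m0 = build_profile_matrix(tags, sites, shift=80)
        m1 = build_profile_matrix(moved, moved_sites, shift=80)
        np.testing.assert_array_equal(m0.values, m1.values)

    def test_strand_mirror_invariance(self, rng):
        L = 30_000
        tags = random_tags(rng, chrom_len=L, n=800)
        sites = [make_site(f"s{i}", position=int(p),
                           strand="+" if i % 2 else "-")
                 for i, p in enumerate(rng.integers(2000, 28_000, 10))]
        m0 = build_profile_matrix(tags, sites, shift=80)
        m1 = build_profile_matrix(mirror_tags(tags, L),
                                  [mirror_site(s, L) for s in sites], shift=80)
        np.testing.assert_array_equal(m0.values, m1.values)
        agg0 = aggregate_profile(m0)
        agg1 = aggregate_profile(m1)
        np.testing.assert_array_equal(agg0.mean_score, agg1.mean_score)


class TestAggregateProfile:
    def test_identical_rows_equal_single_smoothed_row(self, rng):
        tags = random_tags(rng)
        site = make_site(position=5000)
        m = build_profile_matrix(tags, [site, site, site], shift=80)
        agg = aggregate_profile(m, smooth_span=5)
        np.testing.assert_allclose(agg.mean_score, moving_average(m.values[0], 5))

    def test_span_one_is_identity(self, rng):
        tags = random_tags(rng)
        m = build_profile_matrix(tags, [make_site(position=5000),
                                        make_site("s2", position=6000)], shift=80)
        agg = aggregate_profile(m, smooth_span=1)
        np.testing.assert_allclose(agg.mean_score, np.nanmean(m.values, axis=0))

    def test_two_row_hand_smoothed(self):
        from polyanuc.profiles import ProfileMatrix
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0],
                           [3.0, 3.0, 3.0, 3.0, 3.0]])
        m = ProfileMatrix(site_ids=["a", "b"], offsets=np.arange(-20, 21, 10),
                          values=values, shift=80, step=10)
        agg = aggregate_profile(m, smooth_span=3)
        col = values.mean(axis=0)  # [2, 2.5, 3, 3.5, 4]
        # shrinking symmetric windows: edges keep their own value
        expected = [col[0], col[:3].mean(), col[1:4].mean(), col[2:].mean(), col[4]]
        np.testing.assert_allclose(agg.mean_score, expected)

    def test_all_missing_column_stays_missing(self):
        from polyanuc.profiles import ProfileMatrix
        values = np.array([[np.nan, 1.0, 2.0], [np.nan, 3.0, 2.0]])
        m = ProfileMatrix(site_ids=["a", "b"], offsets=np.array([-10, 0, 10]),
                          values=values, shift=80, step=10)
        agg = aggregate_profile(m, smooth_span=1)
        assert np.isnan(agg.mean_score[0])
        np.testing.assert_allclose(agg.mean_score[1:], [2.0, 2.0])


class TestMovingAverage:
    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 4)

    def test_nan_inside_window_ignored(self):
        out = moving_average(np.array([1.0, np.nan, 3.0]), 3)
        assert out[1] == 2.0
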