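"""Meta-profile aggregation, transforms and shift statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import okaseq as ok
from okaseq.fragments import Feature, FeatureSet, FragmentRecord
from okaseq.profiles import read_profile, write_profile

from conftest import aggregate_oracle


def feature_set(midpoints, kind="nucleosome_dyad", scores=None, chrom="chrI"):
    scores = scores or [1.0] * len(midpoints)
    return FeatureSet(
        kind, tuple(Feature(chrom, m, s) for m, s in zip(midpoints, scores))
    )


def impulse_profile(window=10, at=0, value=10.0, **kw):
    counts = np.zeros(2 * window + 1)
    counts[at + window] = value
    defaults = dict(feature_kind="nucleosome_dyad", end_kind="five_prime",
                    window=window, counts=counts, n_features=1, n_termini=int(value))
    defaults.update(kw)
    return ok.TerminusProfile(**defaults)


class TestSelectTopOccupied:
    def test_keeps_top_scoring_half(self):
        fs = feature_set([10, 20, 30, 40], scores=[1, 2, 3, 4])
        kept = ok.select_top_occupied(fs, 0.5)
        assert sorted(f.score for f in kept) == [3, 4]

    def test_fraction_one_is_identity(self):
        fs = feature_set([10, 20, 30], scores=[3, 1, 2])
        assert set(ok.select_top_occupied(fs, 1.0).records) == set(fs.records)

    def test_ties_broken_deterministically(self):
        fs = feature_set([30, 10, 20], scores=[5, 5, 5])
        kept = ok.select_top_occupied(fs, 0.5)  # ceil(1.5) = 2
        assert [f.midpoint for f in kept] == [10, 20]

    def test_errors(self):
        fs = feature_set([10], scores=[1])
        with pytest.raises(ValueError):
            ok.select_top_occupied(FeatureSet("nucleosome_dyad", ()), 0.5)
        with pytest.raises(ValueError):
            ok.select_top_occupied(fs, 0.0)
        with pytest.raises(ValueError):
            ok.select_top_occupied(fs, 1.5)
        with pytest.raises(ValueError):
            ok.select_top_occupied(feature_set([10], kind="tf_site"), 0.5)


class TestAggregateTermini:
    def test_plus_strand_five_prime_offset(self):
        frags = [FragmentRecord("chrI", 95, 260, "+")]
        p = ok.aggregate_termini(frags, feature_set([100]), "five_prime", 50)
        assert p.counts[-5 + 50] == 1 and p.n_termini == 1

    def test_minus_strand_offset_is_flipped(self):
        frags = [FragmentRecord("chrI", 90, 105, "-")]  # 5' at 104
        p = ok.aggregate_termini(frags, feature_set([100]), "five_prime", 50)
        assert p.counts[-4 + 50] == 1  # 100 - 104 in synthesis orientation

    def test_terminus_near_two_features_counts_twice(self):
        frags = [FragmentRecord("chrI", 80, 200, "+")]  # 5' at 80
        p = ok.aggregate_termini(frags, feature_set([100, 40]), "five_prime", 100)
        assert p.n_termini == 2 and p.counts.sum() == 2

    def test_counts_conserve_terminus_feature_pairs(self):
        rng = np.random.default_rng(0)
        frags = [
            FragmentRecord("chrI", int(s), int(s) + int(l), str(st))
            for s, l, st in zip(rng.integers(0, 5000, 300),
                                rng.integers(50, 400, 300),
                                rng.choice(["+", "-"], 300))
        ]
        fs = feature_set(list(range(100, 5000, 250)))
        p = ok.aggregate_termini(frags, fs, "three_prime", 120)
        assert p.counts.sum() == p.n_termini

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        frags = [
            FragmentRecord(rng.choice(["chrI", "chrII"]), int(s), int(s) + int(l),
                           rng.choice(["+", "-"]))
            for s, l in zip(rng.integers(0, 3000, 100), rng.integers(1, 500, 100))
        ]
        feats = FeatureSet(
            "tf_site",
            tuple(Feature(rng.choice(["chrI", "chrII"]), int(m))
                  for m in rng.choice(3000, size=10, replace=False)),
        )
        for end_kind in ("five_prime", "three_prime"):
            p = ok.aggregate_termini(frags, feats, end_kind, 75)
            np.testing.assert_array_equal(
                p.counts, aggregate_oracle(frags, feats, end_kind, 75))

    def test_empty_features_error_empty_fragments_warn(self):
        with pytest.raises(ValueError):
            ok.aggregate_termini([], FeatureSet("tf_site", ()), "five_prime", 10)
        with pytest.warns(UserWarning, match="empty fragment list"):
            p = ok.aggregate_termini([], feature_set([100]), "five_prime", 10)
        assert not p.counts.any() and p.n_termini == 0


class TestSmoothing:
    def test_impulse_spreads_to_window_mean(self):
        sm = ok.smooth_profile(impulse_profile(), 5)
        np.testing.assert_allclose(sm.counts[8:13], 2.0)  # offsets -2..+2
        assert sm.counts[7] == 0 and sm.counts[13] == 0

    def test_width_one_is_identity(self):
        p = impulse_profile()
        np.testing.assert_array_equal(ok.smooth_profile(p, 1).counts, p.counts)

    def test_constant_profile_fixed_including_edges(self):
        p = impulse_profile()
        p.counts[:] = 3.5
        np.testing.assert_allclose(ok.smooth_profile(p, 5).counts, 3.5)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ok.smooth_profile(impulse_profile(), 4)


class TestNormalization:
    def test_max_and_median_modes(self):
        p = impulse_profile(window=1)
        p.counts[:] = [2.0, 4.0, 8.0]
        np.testing.assert_allclose(
            ok.normalize_profile(p, "max").counts, [0.25, 0.5, 1.0])
        np.testing.assert_allclose(
            ok.normalize_profile(p, "median").counts, [0.5, 1.0, 2.0])

    def test_idempotent_and_exact(self):
        p = impulse_profile(window=1)
        p.counts[:] = [2.0, 4.0, 8.0]
        once = ok.normalize_profile(p, "max")
        twice = ok.normalize_profile(once, "max")
        assert once.counts.max() == 1.0
        np.testing.assert_array_equal(once.counts, twice.counts)
        med = ok.normalize_profile(p, "median")
        assert np.median(med.counts) == 1.0

    def test_degenerate_profiles_rejected(self):
        zero = impulse_profile(value=0.0, n_termini=0)
        with pytest.raises(ValueError, match="all-zero"):
            ok.normalize_profile(zero, "max")
        spike = impulse_profile(window=5)  # median 0, max > 0
        with pytest.raises(ValueError, match="median"):
            ok.normalize_profile(spike, "median")


class TestPeakAndCompare:
    def test_impulse_peak_at_zero(self):
        assert ok.profile_peak_offset(impulse_profile()) == 0

    def test_tie_goes_to_negative_offset(self):
        p = impulse_profile()
        p.counts[-3 + 10] = 10.0
        p.counts[3 + 10] = 10.0
        p.counts[10] = 0.0
        assert ok.profile_peak_offset(p) == -3

    def test_all_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            ok.profile_peak_offset(impulse_profile(value=0.0, n_termini=0))

    def _gaussian_profile(self, window=100, mu=0.0):
        x = np.arange(-window, window + 1)
        counts = np.exp(-0.5 * ((x - mu) / 12.0) ** 2) * 100 + 1
        return ok.TerminusProfile("nucleosome_dyad", "three_prime", window,
                                  counts, 10, 1000)

    def test_translation_recovered(self):
        a = self._gaussian_profile()
        b = self._gaussian_profile()
        b.counts[:] = np.roll(a.counts, 7)  # b displaced by +7 offsets
        assert ok.compare_profiles(a, b) == pytest.approx(7.0, abs=0.3)

    def test_self_comparison_is_zero(self):
        a = self._gaussian_profile()
        assert ok.compare_profiles(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_fractional_shift_resolved_subnucleotide(self):
        a = self._gaussian_profile(mu=0.0)
        b = self._gaussian_profile(mu=-3.4)
        assert ok.compare_profiles(a, b) == pytest.approx(-3.4, abs=0.2)

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ok.compare_profiles(self._gaussian_profile(100), self._gaussian_profile(80))

    def test_decoupling_requires_matching_end_kinds(self):
        a = self._gaussian_profile()
        with pytest.raises(ValueError, match="five_prime"):
            ok.end_decoupling_statistic(a, a)

    def test_identical_end_profiles_are_coupled(self):
        p3 = self._gaussian_profile()
        p5 = ok.TerminusProfile("nucleosome_dyad", "five_prime", 100,
                                p3.counts.copy(), 10, 1000)
        delta, verdict = ok.end_decoupling_statistic(p5, p3)
        assert delta == pytest.approx(0.0, abs=1e-9) and verdict == "coupled"


class TestLengthAutocorrelation:
    def test_exact_ladder_recovers_repeat(self):
        frags = [FragmentRecord("c", 0, L, "+")
                 for L in (165, 330, 495) for _ in range(400)]
        lag, score = ok.length_autocorrelation(frags, max_lag=400)
        assert lag == 165 and score > 0.3

    def test_empty_rejected_small_warned(self):
        with pytest.raises(ValueError):
            ok.length_autocorrelation([])
        frags = [FragmentRecord("c", 0, 165, "+")] * 200 + \
                [FragmentRecord("c", 0, 330, "+")] * 100
        with pytest.warns(UserWarning, match="unstable"):
            ok.length_autocorrelation(frags)


class TestProfileIO:
    def test_round_trip_preserves_metadata_and_values(self, tmp_path):
        p = impulse_profile(window=6, at=2, value=9.0)
        sm = ok.normalize_profile(ok.smooth_profile(p, 3), "max")
        path = tmp_path / "p.tsv"
        write_profile(sm, path)
        back = read_profile(path)
        np.testing.assert_allclose(back.counts, sm.counts)
        np.testing.assert_allclose(back.raw_counts, sm.raw_counts)
        for key in ("feature_kind", "end_kind", "window", "smoothing_bp",
                    "normalization", "n_features", "n_termini"):
            assert getattr(back, key) == getattr(sm, key)
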