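"""Border score, peak calling, region lengths and cross-sample alignment."""

import numpy as np
import pandas as pd
import pytest

from midgutlam import BorderScore, BorderSet, align_samples, border_score, \
    call_borders, region_lengths
from midgutlam.profiles import BinnedProfile


def make_profile(tracks: dict, sample_id="s") -> BinnedProfile:
    n = len(next(iter(tracks.values())))
    table = pd.DataFrame({k: np.asarray(v, float) for k, v in tracks.items()},
                         index=pd.RangeIndex(n, name="bin"))
    return BinnedProfile(sample_id=sample_id, n_bins=n, table=table,
                         ploidy_threshold=np.nan)


def step_profile(n_bins=100, step_at=50, lo=100.0, hi=200.0):
    width = np.where(np.arange(n_bins) < step_at, lo, hi)
    const = np.full(n_bins, 7.0)
    return make_profile({"width": width, "large_area": const,
                         "nn_distance": const, "total_count": const})


class TestBorderScore:
    def test_constant_tracks_score_zero(self):
        const = np.full(60, 3.0)
        prof = make_profile({"width": const, "large_area": const,
                             "nn_distance": const, "total_count": const})
        score = border_score([prof])
        s = score.score[score.scorable()]
        assert len(s) > 0 and np.allclose(s, 0.0)

    def test_step_peak_location(self):
        score = border_score([step_profile()], window=5)
        s = np.where(np.isnan(score.score), -np.inf, score.score)
        assert abs(int(np.argmax(s)) - 50) <= 1

    def test_scale_invariance(self):
        p1 = step_profile()
        p2 = step_profile()
        p2.table["width"] *= 10.0
        s1 = border_score([p1]).score
        s2 = border_score([p2]).score
        assert np.allclose(s1, s2, equal_nan=True, rtol=1e-9)

    def test_terminus_bins_unscorable(self):
        score = border_score([step_profile()], window=5, edge_exclude=4)
        assert np.all(np.isnan(score.score[:9]))
        assert np.all(np.isnan(score.score[-10:]))
        assert np.any(~np.isnan(score.score))

    def test_reversal_symmetry(self, cohort_profiles):
        # reversing the A/P orientation reverses the score about the
        # half-bin boundary: score_rev[b] = score[n - 2 - b]
        fwd = border_score(cohort_profiles).score
        rev_profiles = []
        for p in cohort_profiles:
            t = p.table.iloc[::-1].reset_index(drop=True)
            t.index.name = "bin"
            rev_profiles.append(BinnedProfile(
                sample_id=p.sample_id, n_bins=p.n_bins, table=t,
                ploidy_threshold=p.ploidy_threshold))
        rev = border_score(rev_profiles).score
        n = len(fwd)
        for b in range(n):
            m = n - 2 - b
            if 0 <= m < n and not (np.isnan(fwd[m]) or np.isnan(rev[b])):
                assert rev[b] == pytest.approx(fwd[m], rel=1e-9)

    def test_all_missing_variable_errors(self):
        prof = step_profile()
        prof.table["nn_distance"] = np.nan
        with pytest.raises(ValueError, match="nn_distance"):
            border_score([prof])


class TestCallBorders:
    def make_score(self, peaks, n_bins=100, w=5):
        s = np.zeros(n_bins)
        for b, h in peaks:
            s[b] = h
        s[:w] = np.nan
        s[-w:] = np.nan
        return BorderScore(score=s, contributions={}, window=w,
                           weights={}, n_bins=n_bins)

    def test_four_separated_peaks(self):
        score = self.make_score([(19, 5.0), (44, 4.0), (54, 6.0), (84, 3.0)])
        borders = call_borders(score, k=4)
        assert borders.bins.tolist() == [19, 44, 54, 84]
        assert borders.labels == ("B1", "B2", "B3", "B4")
        assert np.allclose(borders.u, [0.20, 0.45, 0.55, 0.85])

    def test_suppression_error(self):
        score = self.make_score([(40, 5.0), (42, 4.0)])
        with pytest.raises(ValueError, match="only 1"):
            call_borders(score, k=2, min_separation=5)

    def test_border_recovery_on_synthetic_cohort(self, default_config,
                                                 cohort_profiles):
        from midgutlam import BorderDetector
        det = BorderDetector().fit(cohort_profiles)
        true_bins = np.round(default_config.border_u * 100).astype(int) - 1
        assert len(det.borders_.bins) == 4
        assert np.all(np.abs(det.borders_.bins - true_bins) <= 3)


class TestRegionLengths:
    def borders(self):
        return BorderSet(bins=np.array([19, 44, 54, 84]),
                         u=np.array([0.2, 0.45, 0.55, 0.85]), n_bins=100)

    def test_arithmetic(self):
        lengths = region_lengths(self.borders(), 3000.0)
        assert lengths["R2"]["um"] == pytest.approx(750.0)
        assert lengths["R2"]["bins"] == 25

    def test_lengths_sum_to_total(self):
        lengths = region_lengths(self.borders(), 3000.0)
        assert sum(v["um"] for v in lengths.values()) == pytest.approx(3000.0)
        assert sum(v["u"] for v in lengths.values()) == pytest.approx(1.0)


class TestAlignSamples:
    def random_border_sets(self, n, rng):
        sets = []
        for _ in range(n):
            bins = np.sort(rng.choice(np.arange(5, 95), 4, replace=False))
            while np.any(np.diff(bins) < 2):
                bins = np.sort(rng.choice(np.arange(5, 95), 4, replace=False))
            sets.append(BorderSet(bins=bins, u=(bins + 1) / 100, n_bins=100))
        return sets

    def test_identity_for_reference_sample(self):
        b = BorderSet(bins=np.array([19, 44, 54, 84]),
                      u=np.array([0.2, 0.45, 0.55, 0.85]), n_bins=100)
        warps = align_samples([b, b, b])
        u = np.linspace(0, 1, 101)
        assert np.allclose(warps[0](u), u)

    def test_borders_map_to_reference(self):
        rng = np.random.default_rng(21)
        sets = self.random_border_sets(5, rng)
        warps = align_samples(sets)
        ref = np.median(np.vstack([b.u for b in sets]), axis=0)
        for b, w in zip(sets, warps):
            assert np.allclose(w(b.u), ref)

    def test_warp_strictly_increasing(self):
        # checked on 100 random monotone border sets
        rng = np.random.default_rng(22)
        sets = self.random_border_sets(100, rng)
        warps = align_samples(sets)
        u = np.linspace(0, 1, 501)
        for w in warps:
            assert np.all(np.diff(w(u)) > 0)

    def test_non_monotone_borders_name_sample(self):
        good = BorderSet(bins=np.array([10, 20, 30, 40]),
                         u=np.array([0.11, 0.21, 0.31, 0.41]), n_bins=100)
        bad = BorderSet(bins=np.array([10, 20, 30, 40]),
                        u=np.array([0.11, 0.21, 0.31, 0.41]), n_bins=100)
        bad.u = np.array([0.11, 0.31, 0.21, 0.41])  # corrupt after init
        with pytest.raises(ValueError, match="badger"):
            align_samples([good, bad], sample_ids=["ok", "badger"])
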