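"""Perceptual-change covariates: oracle equivalence and properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from filmseg import features
from filmseg.features import (ToyPyramidExtractor, hist_distance, imed,
                              imncc, layered_feature_corr, luminance_diff,
                              psd_measures, shot_flags, svd_compact,
                              volume_diff, window_change)


def dense_g_matrix(shape, sigma, neighborhood=None):
    """Full pixel-pair proximity matrix G (optionally truncated), as a dense
    quadratic form — the brute-force oracle for imed/imncc."""
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pos = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    g = np.exp(-d2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)
    if neighborhood is not None:
        r = neighborhood // 2
        off = np.abs(pos[:, None, :] - pos[None, :, :])
        g[(off[..., 0] > r) | (off[..., 1] > r)] = 0.0
    return g


def imed_oracle(a, b, sigma, neighborhood=None):
    d = (np.asarray(a, float) - np.asarray(b, float)).ravel()
    g = dense_g_matrix(a.shape, sigma, neighborhood)
    return float(np.sqrt(max(d @ g @ d, 0.0)))


def imncc_oracle(a, b, sigma, neighborhood=None):
    a = np.asarray(a, float) - np.asarray(a, float).mean()
    b = np.asarray(b, float) - np.asarray(b, float).mean()
    g = dense_g_matrix(a.shape, sigma, neighborhood)
    av, bv = a.ravel(), b.ravel()
    return float((av @ g @ bv)
                 / np.sqrt((av @ g @ av) * (bv @ g @ bv)))


class TestImed:
    def test_identical_frames_zero(self):
        f = np.random.default_rng(0).random((6, 6))
        assert imed(f, f) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert imed(a, b) == pytest.approx(imed(b, a), abs=1e-12)

    def test_matches_dense_quadratic_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert imed(a, b, sigma=1.0) == pytest.approx(
            imed_oracle(a, b, 1.0, neighborhood=9), abs=1e-6)

    def test_truncation_vacuous_on_small_frames(self):
        # every pixel pair of a 5x5 frame lies inside the 9x9 neighborhood,
        # so the truncated distance equals the full-G distance
        rng = np.random.default_rng(3)
        a, b = rng.random((5, 5)), rng.random((5, 5))
        assert imed(a, b, sigma=1.0) == pytest.approx(
            imed_oracle(a, b, 1.0, neighborhood=None), abs=1e-6)

    def test_truncation_error_decreases_with_neighborhood(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((9, 9)), rng.random((9, 9))
        full = imed_oracle(a, b, sigma=2.0)
        errs = [abs(imed(a, b, sigma=2.0, neighborhood=n) - full)
                for n in (3, 7, 11)]
        assert errs[0] > errs[1] > errs[2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(float, (6, 6), elements=st.floats(0, 1)),
           arrays(float, (6, 6), elements=st.floats(0, 1)))
    def test_pseudometric_properties(self, a, b):
        assert imed(a, a) == 0.0
        d_ab, d_ba = imed(a, b), imed(b, a)
        assert d_ab >= 0.0
        assert d_ab == pytest.approx(d_ba, abs=1e-10)

    def test_rgb_channels_summed(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((4, 4, 3)), rng.random((4, 4, 3))
        per_channel = sum(imed(a[..., c], b[..., c]) ** 2 for c in range(3))
        assert imed(a, b) ** 2 == pytest.approx(per_channel, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            imed(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_downscaling_preserves_pair_ordering(self):
        # coarse easy/hard pairs keep their ordering after 1/8 downscaling
        rng = np.random.default_rng(6)
        base = rng.random((32, 32))
        near = base + rng.normal(0, 0.02, base.shape)
        far = rng.random((32, 32))
        small = lambda f: f.reshape(4, 8, 4, 8).mean(axis=(1, 3))
        assert imed(base, near) < imed(base, far)
        assert imed(small(base), small(near)) < imed(small(base), small(far))


class TestImncc:
    def test_identical_frames_one(self):
        f = np.random.default_rng(0).random((6, 6))
        assert imncc(f, f) == pytest.approx(1.0, abs=1e-12)

    def test_negative_of_centered_frame(self):
        f = np.random.default_rng(1).random((6, 6))
        fc = f - f.mean()
        assert imncc(fc, -fc) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((5, 5)), rng.random((5, 5))
        assert imncc(a, b, sigma=1.0) == pytest.approx(
            imncc_oracle(a, b, 1.0), abs=1e-6)


class TestHistogramAndLuminance:
    def test_identical_zero(self):
        f = np.random.default_rng(0).random((8, 8))
        assert hist_distance(f, f) == 0.0

    def test_invariant_to_pixel_permutation(self):
        rng = np.random.default_rng(1)
        f = rng.random((8, 8))
        g = rng.permutation(f.ravel()).reshape(8, 8)
        assert hist_distance(f, g) == 0.0

    def test_hand_computed_toy(self):
        # 4 bins on [0,1]: a has counts [2,2,0,0], b has [2,0,2,0]
        a = np.array([[0.1, 0.2], [0.3, 0.4]])
        b = np.array([[0.1, 0.2], [0.6, 0.7]])
        assert hist_distance(a, b, n_bins=4) == pytest.approx(np.sqrt(8))

    def test_luminance_difference(self):
        assert luminance_diff(np.full((4, 4), 0.3),
                              np.full((4, 4), 0.5)) == pytest.approx(0.2)

    def test_luminance_matches_direct_computation(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((6, 6, 3)), rng.random((6, 6, 3))
        assert luminance_diff(a, b) == pytest.approx(
            abs(a.mean() - b.mean()), abs=1e-12)


class TestWindowChange:
    def _frames(self, per_second=2, n_seconds=6):
        times = np.arange(0, n_seconds, 1 / per_second)
        frames = np.stack([np.full((4, 4), 0.5) for _ in times])
        return frames, times

    def test_static_scene(self):
        frames, times = self._frames()
        assert window_change(frames, times, 3.0, imed, mode="max-dist") == 0.0
        assert window_change(frames, times, 3.0, imncc,
                             mode="min-corr") == pytest.approx(1.0)

    def test_single_changed_frame_dominates_max(self):
        frames, times = self._frames()
        frames = frames.copy()
        idx = np.nonzero(times == 3.5)[0][0]
        frames[idx] = 0.9
        val = window_change(frames, times, 3.0, luminance_diff,
                            mode="max-dist")
        assert val == pytest.approx(0.4)

    def test_window_truncated_at_run_start(self):
        frames, times = self._frames()
        assert window_change(frames, times, 0.2, imed,
                             mode="max-dist") == 0.0


class TestAudioMeasures:
    def test_identical_epochs(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(0, 0.2, 4000)
        audio = np.concatenate([seg, seg])
        corr, dist = psd_measures(audio, 8000, boundary_time=0.5)
        assert corr == pytest.approx(1.0, abs=1e-9)
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_pure_tones_decorrelated(self):
        rate = 8000
        t = np.arange(rate) / rate
        audio = np.concatenate([np.sin(2 * np.pi * 440 * t),
                                np.sin(2 * np.pi * 2000 * t)])
        corr, _ = psd_measures(audio, rate, boundary_time=1.0)
        assert corr < 0.1

    def test_matched_colored_spectra_correlate(self):
        # same spectral shape on both sides: the shared structure dominates
        # the independent periodogram noise, so the PSDs correlate strongly
        from scipy.signal import lfilter
        rng = np.random.default_rng(1)
        rate = 8000
        audio = lfilter([1.0], [1.0, -0.95], rng.normal(0, 0.3, rate * 8))
        corr, _ = psd_measures(audio, rate, boundary_time=4.0, epoch=3.0,
                               f_cutoff=4000.0)
        assert corr > 0.3

    def test_volume_difference_constructed(self):
        rate = 8000
        pre = np.full(800, 0.1)
        post = np.full(800, 0.3)
        audio = np.concatenate([pre, post])
        # RMS of a constant is its absolute value
        assert volume_diff(audio, rate, boundary_time=0.1,
                           window=0.1) == pytest.approx(0.2)

    def test_silence_both_sides(self):
        audio = np.zeros(1600)
        assert volume_diff(audio, 8000, boundary_time=0.1) == 0.0


class TestLayeredFeatures:
    def test_identical_frames_all_ones(self):
        rng = np.random.default_rng(0)
        f = rng.random((8, 8))
        frames = np.stack([f] * 6)
        times = np.arange(6) / 2
        out = layered_feature_corr(frames, times, 1.5,
                                   ToyPyramidExtractor(3))
        assert out.shape == (3,)
        assert np.allclose(out, 1.0)

    def test_layer_count_contract(self):
        rng = np.random.default_rng(1)
        frames = rng.random((4, 8, 8))
        times = np.arange(4) / 2
        out = layered_feature_corr(frames, times, 1.0,
                                   ToyPyramidExtractor(5))
        assert len(out) == 5

    def test_matches_hand_computed_pyramid_correlation(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        frames = np.stack([a, b])
        times = np.array([0.5, 1.2])
        ex = ToyPyramidExtractor(2)
        out = layered_feature_corr(frames, times, 1.0, ex, window=1.0)
        for l in range(2):
            ma = ex.layer_maps(a)[l].ravel()
            mb = ex.layer_maps(b)[l].ravel()
            expected = np.corrcoef(ma, mb)[0, 1]
            assert out[l] == pytest.approx(expected, abs=1e-10)


class TestSvdCompact:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(0)
        u = rng.random(20)
        x = np.outer(u, [1.0, 2.0, -0.5])
        scores, ratio = svd_compact(x, variance_target=0.90)
        assert scores.shape[1] == 1
        assert ratio[0] == pytest.approx(1.0)

    def test_equal_variance_needs_ninety_percent_of_columns(self):
        # exactly orthogonal equal-norm columns: each component carries 1/m
        m, n = 10, 40
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((n, m)))
        scores, _ = svd_compact(q * np.sqrt(n), variance_target=0.90)
        assert scores.shape[1] == int(np.ceil(0.9 * m))

    def test_duplicated_column_does_not_add_components(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 4))
        xd = np.column_stack([x, x[:, 0]])
        k1 = svd_compact(x, variance_target=0.9)[0].shape[1]
        k2 = svd_compact(xd, variance_target=0.9)[0].shape[1]
        assert k2 <= k1 + 1

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 6))
        scores, _ = svd_compact(x, k_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestShotFlags:
    def _shots(self):
        return pd.DataFrame({
            "onset_s": [0.0, 20.0, 40.0, 60.0],
            "location_id": [0, 1, 1, 2],
            "temporal_progression": [0, 1, 0, 1]})

    def test_boundary_at_location_change(self):
        b = pd.DataFrame({"time_s": [20.5]})
        out = shot_flags(b, self._shots(), tr=2.0)
        assert out.loc[0, "isLoc"] == 1
        assert out.loc[0, "isTemp"] == 1

    def test_boundary_far_from_shots_gets_zero_flags(self):
        b = pd.DataFrame({"time_s": [30.0]})
        out = shot_flags(b, self._shots(), tr=2.0)
        assert out.loc[0, "isLoc"] == 0
        assert out.loc[0, "isTemp"] == 0

    def test_coinciding_flags_emit_combined_predictor(self):
        shots = pd.DataFrame({"onset_s": [0.0, 20.0, 40.0],
                              "location_id": [0, 1, 1],
                              "temporal_progression": [0, 1, 0]})
        b = pd.DataFrame({"time_s": [20.2, 40.3]})
        out = shot_flags(b, shots, tr=2.0)
        assert out.attrs["isLocTemp_combined"]
        assert "isLocTemp" in out.columns
        assert out["isLocTemp"].tolist() == [1, 0]
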