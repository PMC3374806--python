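"""Unit tests for the S1/C1/S2/C2 cascade."""

import math
import warnings

import numpy as np
import pytest

from artmax.hierarchy import (
    C1Maps,
    S1Maps,
    apply_s1,
    build_gabor_bank,
    compute_c2,
    extract_patch,
    pool_c1,
    preprocess,
    s2_responses,
    s2_sigma_sq,
)

from conftest import make_toy_c1


class TestPreprocess:
    def test_color_image_rescaled_to_target_height(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 256, size=(280, 400, 3), dtype=np.uint8)
        out = preprocess(raw, target_height=140)
        assert out.shape == (140, 200)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_already_at_height_is_identity(self):
        img = np.random.default_rng(1).random((140, 90))
        assert np.array_equal(preprocess(img, 140), img)

    def test_uniform_gray_stays_uniform(self):
        out = preprocess(np.full((70, 70), 0.5), target_height=140)
        assert np.allclose(out, 0.5)

    def test_zero_area_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.empty((0, 10)))


class TestGaborBank:
    def test_default_bank_composition(self, bank):
        assert len(bank.filters) == 64
        assert bank.sizes == tuple(range(7, 39, 2))
        assert bank.orientations == (0, 45, 90, 135)
        assert bank.bands[0] == (7, 9)
        assert bank.bands[-1] == (35, 37)
        assert all(b[1] - b[0] == 2 for b in bank.bands)

    def test_filters_zero_mean_unit_norm(self, bank):
        for f in bank.filters:
            assert abs(f.weights.sum()) < 1e-6
            assert abs(np.linalg.norm(f.weights) - 1.0) < 1e-6

    def test_even_filter_size_rejected(self):
        with pytest.raises(ValueError):
            build_gabor_bank(sizes=(6, 8), pool_sizes=(8,))


class TestS1:
    def test_constant_image_gives_zero_response(self, bank):
        s1 = apply_s1(np.full((50, 50), 0.7), bank)
        for m in s1.values():
            assert np.all(m < 1e-8)

    def test_window_equal_to_filter_responds_one(self, bank):
        f = bank.filters_for(11)[0]
        img = np.zeros((41, 41))
        img[10:21, 10:21] = f.weights  # the window IS the filter
        s1 = apply_s1(img, bank)
        # center of the embedded filter: valid-map index = position - half
        assert s1[(11, 0)][10, 10] == pytest.approx(1.0, abs=1e-9)

    def test_horizontal_bar_prefers_zero_degrees(self, bank):
        img = np.full((60, 60), 0.5)
        img[28:32, 10:50] = 1.0
        s1 = apply_s1(img, bank)
        r0 = s1[(11, 0)][24, 24]
        r90 = s1[(11, 90)][24, 24]
        assert r0 >= r90

    def test_image_smaller_than_filter_warns_and_empty(self, bank):
        with pytest.warns(UserWarning, match="smaller than"):
            s1 = apply_s1(np.random.default_rng(0).random((20, 20)), bank)
        assert s1[(37, 0)].size == 0
        assert s1[(19, 0)].size > 0

    def test_responses_bounded(self, bank):
        img = np.random.default_rng(3).random((60, 60))
        s1 = apply_s1(img, bank)
        for m in s1.values():
            assert m.min() >= 0.0 and m.max() <= 1.0


class TestC1:
    def _tiny_bank(self):
        # one band (sizes 7, 9) pooled over a 2x2 grid, stride 1
        return build_gabor_bank(sizes=(7, 9), pool_sizes=(2,))

    def test_single_peak_and_shift_invariance(self):
        bank = self._tiny_bank()
        s1 = S1Maps()
        for theta in bank.orientations:
            s1[(7, theta)] = np.zeros((4, 4))
            s1[(9, theta)] = np.zeros((4, 4))
        ref = None
        for (r, c) in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            s1[(7, 0)] = np.zeros((4, 4))
            s1[(7, 0)][r, c] = 0.6
            c1 = pool_c1(s1, bank)
            assert c1.band(0)[0, 0, 0] == pytest.approx(0.6)
            if ref is None:
                ref = c1.band(0)[0, 0, 0]
            assert c1.band(0)[0, 0, 0] == ref  # max is shift invariant

    def test_cross_scale_max_by_hand(self):
        bank = self._tiny_bank()
        s1 = S1Maps()
        for theta in bank.orientations:
            s1[(7, theta)] = np.zeros((2, 2))
            s1[(9, theta)] = np.zeros((2, 2))
        s1[(7, 45)] = np.array([[0.2, 0.1], [0.0, 0.3]])
        s1[(9, 45)] = np.array([[0.25, 0.1], [0.1, 0.1]])
        c1 = pool_c1(s1, bank)
        # window covers both cells of both scales: max of all eight values
        assert c1.band(0)[0, 0, 1] == pytest.approx(0.3)


class TestPatchesAndS2:
    def test_extract_patch_copies_verbatim(self, toy_c1):
        p = extract_patch(toy_c1, band=0, row=3, col=5, n=4, proto_id=7)
        assert p.values.shape == (4, 4, 4)
        assert np.array_equal(p.values, toy_c1.band(0)[3:7, 5:9, :])
        assert p.provenance == (-1, 0, 3, 5)
        # mutating the copy must not touch the source
        p.values[0, 0, 0] = -1
        assert toy_c1.band(0)[3, 5, 0] != -1

    def test_out_of_bounds_patch_rejected(self, toy_c1):
        with pytest.raises(IndexError):
            extract_patch(toy_c1, band=1, row=16, col=0, n=4)

    def test_zero_patch_flagged_low_energy(self):
        c1 = C1Maps(bands=(np.zeros((8, 8, 4)),))
        with pytest.warns(UserWarning, match="low-energy"):
            p = extract_patch(c1, 0, 0, 0, 4)
        assert p.is_low_energy

    def test_identical_window_gives_response_one(self, toy_c1):
        p = extract_patch(toy_c1, band=0, row=2, col=2, n=8)
        resp = s2_responses(toy_c1, p)
        assert resp[0][2, 2] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_at_one_sigma(self):
        # squared distance of exactly 2 sigma_n^2 must give e^-1
        n, s = 4, 0.3
        c1 = C1Maps(bands=(np.zeros((n, n, 4)),))
        delta = math.sqrt(2.0 * s2_sigma_sq(n, s) / (4 * n * n))
        p = extract_patch(c1, 0, 0, 0, n)
        object.__setattr__(p, "values", np.full((n, n, 4), delta))
        r = s2_responses(c1, p, sharpness=s)
        assert r[0][0, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_responses_in_unit_interval(self, toy_c1):
        p = extract_patch(toy_c1, 0, 0, 0, 8)
        for r in s2_responses(toy_c1, p):
            if r is not None:
                assert np.all(r > 0) and np.all(r <= 1)

    def test_patch_too_large_for_every_band_errors(self):
        c1 = C1Maps(bands=(np.random.default_rng(0).random((6, 6, 4)),))
        p = extract_patch(make_toy_c1(np.random.default_rng(1),
                                      shapes=((12, 12),)), 0, 0, 0, 8)
        with pytest.raises(ValueError):
            s2_responses(c1, p)


def brute_force_c2(c1, prototypes, sharpness):
    """Independent exhaustive scan: plain Python loops, no shortcuts."""
    out = []
    for p in prototypes:
        n = p.size
        best = None
        for grid in c1.bands:
            h, w, _ = grid.shape
            for r in range(h - n + 1):
                for c in range(w - n + 1):
                    d2 = 0.0
                    for i in range(n):
                        for j in range(n):
                            for o in range(4):
                                diff = grid[r + i, c + j, o] - p.values[i, j, o]
                                d2 += diff * diff
                    val = math.exp(-d2 / (2.0 * sharpness * 4 * n * n))
                    best = val if best is None else max(best, val)
        out.append(best)
    return np.array(out)


class TestC2:
    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        c1 = make_toy_c1(rng, shapes=((12, 14), (8, 9)))
        protos = [extract_patch(c1, 0, int(rng.integers(8)),
                                int(rng.integers(10)), 4, proto_id=i)
                  for i in range(3)]
        got = compute_c2(c1, protos, sharpness=0.01)
        want = brute_force_c2(c1, protos, sharpness=0.01)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_vector_length_tracks_pool(self, toy_c1):
        protos = [extract_patch(toy_c1, 0, i, i, 4, proto_id=i)
                  for i in range(6)]
        assert compute_c2(toy_c1, protos).shape == (6,)
        assert compute_c2(toy_c1, []).shape == (0,)

    def test_self_match_is_one_anywhere(self, toy_c1):
        for (r, c) in [(0, 0), (5, 11), (22, 26)]:
            p = extract_patch(toy_c1, 0, r, c, 4)
            assert compute_c2(toy_c1, [p])[0] == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_appending_prototype_is_prefix_stable(self, toy_c1):
        protos = [extract_patch(toy_c1, 0, 2 * i, i, 4, proto_id=i)
                  for i in range(5)]
        short = compute_c2(toy_c1, protos[:3])
        full = compute_c2(toy_c1, protos)
        np.testing.assert_array_equal(short, full[:3])

    def test_position_tolerance_of_embedded_pattern(self):
        rng = np.random.default_rng(7)
        pattern = rng.random((4, 4, 4))
        for (r, c) in [(0, 0), (10, 3), (20, 24)]:
            grid = rng.random((26, 30, 4))
            grid[r:r + 4, c:c + 4, :] = pattern
            c1 = C1Maps(bands=(grid,))
            p = extract_patch(C1Maps(bands=(pattern.copy(),)), 0, 0, 0, 4)
            assert compute_c2(c1, [p])[0] == pytest.approx(1.0, abs=1e-12)
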