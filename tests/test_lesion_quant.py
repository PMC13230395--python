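import itertools
import warnings

import numpy as np
import pytest

from fastpetdn.lesion_quant import (
    ReaderPanel,
    SegmentationParams,
    detect_candidates,
    extract_features,
    match_and_score,
    mtv_filter,
    segment_lesion,
    suv_peak,
)
from fastpetdn.phantom import NoiseParams, simulate_acquisition
from fastpetdn.volio import Volume


def _hot_sphere(shape=(32, 32, 32), spacing=4.0, center=None, diameter=24.0, suv=5.0, bg=1.0):
    axes = [(np.arange(n) + 0.5) * spacing for n in shape]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    center = center or tuple(n * spacing / 2 for n in shape)
    d2 = np.sum((pts - np.asarray(center)) ** 2, axis=-1)
    inside = d2 <= (diameter / 2) ** 2
    data = np.full(shape, bg, dtype=np.float32)
    data[inside] = suv
    return Volume(data, (spacing,) * 3), inside, center


class TestSegmentation:
    def test_recovers_sphere_within_one_voxel_layer(self):
        vol, truth, center = _hot_sphere()
        mask = segment_lesion(vol, center)
        # within one voxel layer of the true sphere: all true voxels found,
        # no voxel further than one layer outside
        from scipy import ndimage

        dilated = ndimage.binary_dilation(truth)
        eroded = ndimage.binary_erosion(truth)
        assert mask[eroded].all()
        assert not mask[~dilated].any()

    def test_uniform_background_seed_gives_empty_mask(self):
        vol = Volume(np.full((24, 24, 24), 1.0, dtype=np.float32), (4.0,) * 3)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mask = segment_lesion(vol, (48.0, 48.0, 48.0))
        assert not mask.any()
        assert any("contrast" in str(w.message) for w in caught)

    def test_threshold_fraction_one_keeps_only_the_maximum(self):
        vol, truth, center = _hot_sphere()
        # make a unique maximum voxel at the seed itself
        idx = (16, 16, 16)
        assert truth[idx]
        vol.data[idx] = 9.0
        mask = segment_lesion(vol, center, SegmentationParams(threshold_fraction=1.0))
        assert mask.sum() == 1
        assert mask[idx]

    def test_deterministic(self):
        vol, _, center = _hot_sphere()
        noisy = simulate_acquisition(
            Volume(vol.data, vol.voxel_size_mm), NoiseParams(duration_fraction=0.5), seed=3
        )
        m1 = segment_lesion(noisy, center)
        m2 = segment_lesion(noisy, center)
        assert np.array_equal(m1, m2)


class TestMTVFilter:
    def test_four_voxels_at_4mm_is_0p256_and_kept(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, :4] = True
        keep, mtv = mtv_filter(mask, (4.0, 4.0, 4.0))
        assert keep
        assert mtv == pytest.approx(0.256)

    def test_three_voxels_dropped(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, :3] = True
        keep, mtv = mtv_filter(mask, (4.0, 4.0, 4.0))
        assert not keep
        assert mtv == pytest.approx(0.192)

    def test_rule_is_voxel_count_based(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, :4] = True
        keep, mtv = mtv_filter(mask, (2.0, 2.0, 2.0))
        assert keep
        assert mtv == pytest.approx(0.032)


class TestFeatures:
    def test_uniform_lesion_features(self):
        vol, truth, _ = _hot_sphere(suv=3.0)
        f = extract_features(vol, truth, lesion_id=7)
        assert f.suv_max == pytest.approx(3.0)
        assert f.suv_mean == pytest.approx(3.0)
        assert f.mtv_cm3 == pytest.approx(truth.sum() * 0.064)
        assert f.tlg_g == f.suv_mean * f.mtv_cm3  # exact identity, bitwise

    def test_tlg_identity_on_noisy_lesion(self, rng):
        vol, truth, center = _hot_sphere()
        vol.data += rng.normal(0, 0.3, vol.shape).astype(np.float32)
        f = extract_features(vol, truth)
        assert f.tlg_g == f.suv_mean * f.mtv_cm3
        assert f.suv_mean <= f.suv_max
        assert f.suv_peak <= f.suv_max

    def test_suv_peak_matches_brute_force_sphere_mean(self, rng):
        data = rng.uniform(1.0, 6.0, size=(9, 9, 9)).astype(np.float32)
        vol = Volume(data, (4.0,) * 3)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        got = suv_peak(vol, mask, radius_mm=6.2)
        # oracle: direct sphere-mean at every in-mask center
        best = -np.inf
        padded = np.pad(data.astype(np.float64), 2, mode="reflect")
        for i, j, k in np.argwhere(mask):
            vals = []
            for oi, oj, ok in itertools.product(range(-2, 3), repeat=3):
                if (4.0 * oi) ** 2 + (4.0 * oj) ** 2 + (4.0 * ok) ** 2 <= 6.2**2:
                    vals.append(padded[i + 2 + oi, j + 2 + oj, k + 2 + ok])
            best = max(best, np.mean(vals))
        assert got == pytest.approx(best, rel=1e-10)

    def test_empty_mask_rejected(self):
        vol, _, _ = _hot_sphere()
        with pytest.raises(ValueError, match="empty"):
            extract_features(vol, np.zeros(vol.shape, dtype=bool))


class TestMatching:
    def test_exact_match_perfect_scores(self):
        pts = [(10.0, 10.0, 10.0), (50.0, 50.0, 50.0), (90.0, 20.0, 30.0)]
        out = match_and_score(pts, pts)
        assert (out.sensitivity, out.ppv) == (1.0, 1.0)
        assert (out.tp, out.fp, out.fn) == (3, 0, 0)

    def test_sensitivity_and_ppv_arithmetic(self):
        truth = [(float(i * 30), 0.0, 0.0) for i in range(10)]
        matched = truth[:7]
        unmatched = [(1000.0, 1000.0, float(i)) for i in range(2)]
        out = match_and_score(list(matched) + unmatched, truth)
        assert out.sensitivity == pytest.approx(0.70)
        assert out.ppv == pytest.approx(7 / 9)

    def test_one_to_one_matching(self):
        # two candidates near one truth lesion: only one TP, the other is FP
        out = match_and_score([(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)], [(1.0, 0.0, 0.0)])
        assert (out.tp, out.fp, out.fn) == (1, 1, 0)

    def test_swap_symmetry_on_random_toys(self, rng):
        for _ in range(10):
            a = [tuple(p) for p in rng.uniform(0, 200, size=(rng.integers(1, 8), 3))]
            b = [tuple(p) for p in rng.uniform(0, 200, size=(rng.integers(1, 8), 3))]
            ab = match_and_score(a, b, tol_mm=25.0)
            ba = match_and_score(b, a, tol_mm=25.0)
            assert ab.tp == ba.tp
            assert ab.sensitivity == pytest.approx(ba.ppv, nan_ok=True)
            assert ab.ppv == pytest.approx(ba.sensitivity, nan_ok=True)

    def test_empty_lists_give_nan_with_warning(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = match_and_score([], [(0.0, 0.0, 0.0)])
        assert np.isnan(out.ppv)
        assert out.sensitivity == 0.0
        assert caught


class TestReaderPanel:
    def test_minority_candidate_excluded(self):
        seen_by_two = (40.0, 40.0, 40.0)
        seen_by_one = (120.0, 120.0, 120.0)
        panel = ReaderPanel(
            [[seen_by_two, seen_by_one], [seen_by_two], []],
            k=2,
        )
        cons = panel.consensus()
        assert len(cons) == 1
        assert np.allclose(cons[0], seen_by_two)

    def test_consensus_feeds_matching(self):
        p1 = (40.0, 40.0, 40.0)
        lone = (120.0, 120.0, 120.0)
        panel = ReaderPanel([[p1, lone], [p1], [p1]], k=2)
        out = match_and_score([], [p1, lone], panel=panel)
        assert (out.tp, out.fn, out.fp) == (1, 1, 0)

    def test_detect_candidates_finds_hot_sphere(self):
        vol, truth, center = _hot_sphere(shape=(32, 32, 48), diameter=20.0)
        body = np.ones(vol.shape, dtype=bool)
        cands = detect_candidates(vol, body)
        assert cands
        d = min(np.linalg.norm(np.subtract(c, center)) for c in cands)
        assert d <= 10.0
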