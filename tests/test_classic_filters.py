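import itertools

import numpy as np
import pytest

from fastpetdn.classic_filters import (
    FilterError,
    GaussianParams,
    NLMParams,
    default_gaussian_grid,
    default_nlm_grid,
    fwhm_to_sigma_mm,
    gaussian_denoise,
    nlm_denoise,
    optimize_filter,
)
from fastpetdn.volio import Volume


def nlm_triple_loop(x: np.ndarray, r: int, d: int, h_abs: float, sigma: float) -> np.ndarray:
    """Direct O(n*w*p) reference implementation of the package's NLM dialect.

    Operates on the reflect-padded array; for voxel i and search offset o the
    patch distance is the plain mean over the (2r+1)^3 patch of squared
    differences, the weight exp(-max(D - 2*sigma^2, 0) / h_abs^2).
    """
    pad = d + r
    xp = np.pad(x.astype(np.float64), pad, mode="symmetric")
    out = np.zeros_like(x, dtype=np.float64)
    patch_offsets = list(itertools.product(range(-r, r + 1), repeat=3))
    search_offsets = list(itertools.product(range(-d, d + 1), repeat=3))
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for k in range(x.shape[2]):
                ci, cj, ck = i + pad, j + pad, k + pad
                num = den = 0.0
                for oi, oj, ok in search_offsets:
                    dist = 0.0
                    for qi, qj, qk in patch_offsets:
                        a = xp[ci + qi, cj + qj, ck + qk]
                        b = xp[ci + oi + qi, cj + oj + qj, ck + ok + qk]
                        dist += (a - b) ** 2
                    dist /= len(patch_offsets)
                    w = np.exp(-max(dist - 2 * sigma * sigma, 0.0) / h_abs**2)
                    num += w * xp[ci + oi, cj + oj, ck + ok]
                    den += w
                out[i, j, k] = num / den
    return out


class TestGaussian:
    def test_fwhm_to_sigma_closed_form(self):
        assert fwhm_to_sigma_mm(5.0) == pytest.approx(2.1233, abs=5e-5)
        # 5 mm FWHM at 4 mm spacing is about half a voxel of SD
        assert fwhm_to_sigma_mm(5.0) / 4.0 == pytest.approx(0.5308, abs=5e-5)

    def test_impulse_response_is_normalized(self):
        data = np.zeros((33, 33, 33), dtype=np.float32)
        data[16, 16, 16] = 1.0
        out = gaussian_denoise(Volume(data, (4.0, 4.0, 4.0)), GaussianParams(5.0))
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_volume_preserved(self):
        vol = Volume(np.full((16, 16, 16), 2.5, dtype=np.float32), (4.0, 4.0, 4.0))
        out = gaussian_denoise(vol, GaussianParams(6.0))
        assert np.allclose(out.data, 2.5, atol=1e-5)

    def test_mass_conservation_with_air_border(self, default_phantom, phantom_truth):
        out = gaussian_denoise(phantom_truth, GaussianParams(5.0))
        total_in = phantom_truth.data.astype(np.float64).sum()
        assert out.data.astype(np.float64).sum() == pytest.approx(total_in, rel=1e-6)

    def test_linearity(self, rng):
        a = Volume(rng.uniform(0, 4, (14, 14, 14)).astype(np.float32), (4.0,) * 3)
        b = Volume(rng.uniform(0, 4, (14, 14, 14)).astype(np.float32), (4.0,) * 3)
        combo = Volume(2.0 * a.data + 3.0 * b.data, (4.0,) * 3)
        p = GaussianParams(5.0)
        lhs = gaussian_denoise(combo, p).data
        rhs = 2.0 * gaussian_denoise(a, p).data + 3.0 * gaussian_denoise(b, p).data
        assert np.allclose(lhs, rhs, atol=1e-4)

    def test_invalid_fwhm(self):
        with pytest.raises(FilterError):
            GaussianParams(0.0)


class TestNLM:
    def test_matches_triple_loop_oracle(self, rng):
        x = rng.uniform(0.5, 3.0, size=(10, 10, 10)).astype(np.float32)
        vol = Volume(x, (4.0,) * 3)
        sigma = 0.2
        for p in (NLMParams(1, 2, 0.3), NLMParams(1, 3, 0.5), NLMParams(2, 2, 0.8)):
            if any(n <= 2 * (p.search_radius_vox + p.patch_radius_vox) for n in x.shape):
                continue
            got = nlm_denoise(vol, p, sigma_est=sigma).data
            want = nlm_triple_loop(x, p.patch_radius_vox, p.search_radius_vox, p.h * sigma, sigma)
            assert np.abs(got - want).max() < 1e-5

    def test_h_to_zero_returns_input_when_noiseless(self, rng):
        x = rng.uniform(0.5, 3.0, size=(12, 12, 12)).astype(np.float32)
        vol = Volume(x, (4.0,) * 3)
        out = nlm_denoise(vol, NLMParams(1, 2, 1e-6), sigma_est=0.0)
        assert np.abs(out.data - x).max() < 1e-5

    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((12, 12, 12), 1.7, dtype=np.float32), (4.0,) * 3)
        out = nlm_denoise(vol, NLMParams(1, 2, 0.3), sigma_est=0.1)
        assert np.allclose(out.data, 1.7, atol=1e-6)

    def test_h_to_infinity_converges_to_window_mean(self, rng):
        # with uniform weights NLM is the plain mean of the (reflect-padded) search window
        x = rng.uniform(0.5, 3.0, size=(9, 9, 9)).astype(np.float32)
        d = 2
        vol = Volume(x, (4.0,) * 3)
        got = nlm_denoise(vol, NLMParams(1, d, 1e6), absolute_h=True).data
        from scipy import ndimage

        want = ndimage.uniform_filter(x.astype(np.float64), size=2 * d + 1, mode="reflect")
        assert np.abs(got - want).max() < 1e-4

    def test_denoises_uniform_region_at_default_parameters(self, rng):
        # uniform SUV 2 region with mixed noise; paper-style params d=3, patch 3^3, h=0.3
        clean = np.full((20, 20, 20), 2.0)
        noisy = (rng.poisson(clean * 20) / 20.0 + rng.normal(0, 0.05, clean.shape)).astype(
            np.float32
        )
        vol = Volume(noisy, (4.0,) * 3)
        out = nlm_denoise(vol, NLMParams(1, 3, 0.3))
        assert out.data.std() < noisy.std()

    def test_radii_validation(self):
        vol = Volume(np.zeros((8, 8, 8), dtype=np.float32), (4.0,) * 3)
        with pytest.raises(FilterError, match="too large"):
            nlm_denoise(vol, NLMParams(1, 3, 0.3), sigma_est=0.1)
        with pytest.raises(FilterError):
            NLMParams(0, 3, 0.3)
        with pytest.raises(FilterError):
            NLMParams(1, 3, 0.0)


class TestOptimize:
    @staticmethod
    def _noisy_pair(rng, sigma=0.4):
        ref = np.zeros((24, 24, 24), dtype=np.float32)
        ref[4:20, 4:20, 4:20] = 2.0
        ref[8:12, 8:12, 8:12] = 5.0
        fast = ref + rng.normal(0, sigma, ref.shape).astype(np.float32)
        spacing = (4.0,) * 3
        return Volume(fast, spacing), Volume(ref, spacing)

    def test_grid_argmin_matches_exhaustive_oracle(self, rng):
        pair = self._noisy_pair(rng)
        grid = default_gaussian_grid()
        best, table = optimize_filter([pair], grid, mask_fn=False)
        assert len(table) == len(grid)
        # oracle: the grid itself, re-evaluated exhaustively
        mses = {
            g.fwhm_mm: np.mean(
                (gaussian_denoise(pair[0], g).data.astype(np.float64) - pair[1].data) ** 2
            )
            for g in grid
        }
        assert best.fwhm_mm == min(mses, key=mses.get)
        for _, row in table.iterrows():
            assert row["mse"] == pytest.approx(mses[row["fwhm_mm"]], rel=1e-6)

    def test_single_element_grid(self, rng):
        pair = self._noisy_pair(rng)
        best, table = optimize_filter([pair], [GaussianParams(4.0)], mask_fn=False)
        assert best.fwhm_mm == 4.0
        assert len(table) == 1

    def test_tie_breaks_toward_weaker_smoothing(self):
        # identical pair -> every fwhm scores near-zero; smallest wins
        ref = Volume(np.full((16, 16, 16), 2.0, dtype=np.float32), (4.0,) * 3)
        best, _ = optimize_filter([(ref, ref)], default_gaussian_grid(), mask_fn=False)
        assert best.fwhm_mm == 3.0

    def test_misaligned_pair_rejected(self, rng):
        a = Volume(np.zeros((12, 12, 12), dtype=np.float32), (4.0,) * 3)
        b = Volume(np.zeros((12, 12, 10), dtype=np.float32), (4.0,) * 3)
        from fastpetdn.volio import AlignmentError

        with pytest.raises(AlignmentError):
            optimize_filter([(a, b)], default_gaussian_grid())

    def test_paper_operating_point_is_in_default_grids(self):
        assert any(g.fwhm_mm == 5.0 for g in default_gaussian_grid())
        assert any(
            p.h == pytest.approx(0.3) and p.search_radius_vox == 3 and p.patch_radius_vox == 1
            for p in default_nlm_grid()
        )
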