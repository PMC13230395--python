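"""Lesion segmentation, SUV feature extraction and detectability scoring.

Segmentation is a deterministic adaptive-threshold region grower: from a seed,
the local maximum is found, the local background is estimated in a surrounding
shell, and the connected component above

    threshold = background + f * (local SUV_max - background)

containing the seed is returned (default f = 0.41). The interface is
deliberately pluggable so a statistically richer segmenter can drop in.

Features per lesion: SUV_max, SUV_mean, SUV_peak (maximum over in-lesion
voxel centers of the mean within a 1 cm^3 sphere, radius 6.2 mm), MTV
(voxel count x voxel volume, cm^3) and TLG = SUV_mean * MTV (g). Lesions are
only quantified when their segmented MTV reaches 4 voxels — 0.256 cm^3 at
4 mm isotropic spacing.

Detectability is scored by one-to-one greedy centroid matching between
candidate and ground-truth lesions (sensitivity = TP/(TP+FN),
PPV = TP/(TP+FP)); a reader panel applies a majority-consensus rule
(candidates kept when >= k of the readers report them) before matching.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volio import LabelMask, Volume, check_aligned

__all__ = [
    "LesionFeatureSet",
    "DetectionOutcome",
    "ReaderPanel",
    "SegmentationParams",
    "segment_lesion",
    "mtv_filter",
    "extract_features",
    "suv_peak",
    "match_and_score",
    "detect_candidates",
    "simulated_reader_panel",
    "MIN_MTV_VOXELS",
]

#: minimum segmented volume for a lesion to enter quantification
MIN_MTV_VOXELS = 4

#: radius of the 1 cm^3 SUV_peak sphere
PEAK_SPHERE_RADIUS_MM = 6.2


@dataclasses.dataclass
class LesionFeatureSet:
    id: int
    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv_cm3: float
    tlg_g: float
    centroid_mm: tuple[float, float, float] | None = None


@dataclasses.dataclass
class DetectionOutcome:
    tp: int
    fp: int
    fn: int
    matched_truth_ids: list[int]
    sensitivity: float
    ppv: float


@dataclasses.dataclass
class ReaderPanel:
    """Candidate centroid lists from several readers plus a consensus rule."""

    reader_candidates: list[list[tuple[float, float, float]]]
    k: int = 2  # candidates kept when identified by >= k readers
    merge_tol_mm: float = 10.0

    def consensus(self) -> list[tuple[float, float, float]]:
        """Merge per-reader candidate lists; keep clusters seen by >= k readers."""
        clusters: list[dict] = []  # {'centroid': array, 'readers': set}
        for ridx, cands in enumerate(self.reader_candidates):
            for c in cands:
                c = np.asarray(c, dtype=np.float64)
                best, best_d = None, self.merge_tol_mm
                for cl in clusters:
                    d = float(np.linalg.norm(cl["centroid"] - c))
                    if d <= best_d:
                        best, best_d = cl, d
                if best is None:
                    clusters.append({"centroid": c, "readers": {ridx}, "pts": [c]})
                else:
                    best["readers"].add(ridx)
                    best["pts"].append(c)
                    best["centroid"] = np.mean(best["pts"], axis=0)
        return [
            tuple(cl["centroid"]) for cl in clusters if len(cl["readers"]) >= self.k
        ]


@dataclasses.dataclass
class SegmentationParams:
    threshold_fraction: float = 0.41  # f in bg + f*(local max - bg)
    search_radius_mm: float = 12.0    # radius to locate the local maximum
    shell_inner_mm: float = 15.0      # background shell around the local max
    shell_outer_mm: float = 25.0
    max_extent_mm: float = 40.0       # cap on region radius: keeps a noisy
                                      # grow from leaking into a whole organ


def _ball_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Integer voxel offsets whose centers lie within radius_mm of the origin."""
    r_vox = [int(math.floor(radius_mm / s)) for s in spacing]
    offs = []
    for i in range(-r_vox[0], r_vox[0] + 1):
        for j in range(-r_vox[1], r_vox[1] + 1):
            for k in range(-r_vox[2], r_vox[2] + 1):
                d = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if d <= radius_mm**2:
                    offs.append((i, j, k))
    return np.asarray(offs, dtype=np.int64)


def _dist_mm_from(shape, spacing, idx) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - i) * s) ** 2 for g, i, s in zip(grids, idx, spacing))
    return np.sqrt(d2)


def segment_lesion(
    vol: Volume,
    seed_point_mm: Sequence[float],
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Adaptive-threshold region growing around a seed; returns a boolean mask.

    Deterministic: local SUV_max within ``search_radius_mm`` of the seed,
    background = median SUV in the [shell_inner, shell_outer] mm shell around
    the peak, threshold = bg + f*(max - bg), mask = connected component of the
    above-threshold voxels containing the peak. An empty result (no contrast)
    returns an all-false mask.
    """
    p = params or SegmentationParams()
    spacing = vol.voxel_size_mm
    idx = tuple(
        int(np.clip(round(c / s - 0.5), 0, n - 1))
        for c, s, n in zip(seed_point_mm, spacing, vol.shape)
    )
    dist = _dist_mm_from(vol.shape, spacing, idx)
    near = dist <= p.search_radius_mm
    data = vol.data.astype(np.float64)
    peak_flat = np.argmax(np.where(near, data, -np.inf))
    peak_idx = np.unravel_index(peak_flat, vol.shape)
    local_max = data[peak_idx]

    dist_pk = _dist_mm_from(vol.shape, spacing, peak_idx)
    shell = (dist_pk >= p.shell_inner_mm) & (dist_pk <= p.shell_outer_mm)
    bg = float(np.median(data[shell])) if shell.any() else 0.0
    if local_max <= bg:
        warnings.warn("segment_lesion: no contrast at seed, empty mask", stacklevel=2)
        return np.zeros(vol.shape, dtype=bool)
    thr = bg + p.threshold_fraction * (local_max - bg)
    above = (data >= thr) & (dist_pk <= p.max_extent_mm)
    lab, _ = ndimage.label(above)
    mask = lab == lab[peak_idx]
    if not mask.any():
        warnings.warn("segment_lesion: empty region", stacklevel=2)
    return mask


def mtv_filter(mask: np.ndarray, voxel_size_mm) -> tuple[bool, float]:
    """Apply the minimum-volume rule; returns (keep, MTV in cm^3).

    Lesions are kept when the segmentation holds at least 4 voxels; the MTV is
    reported as voxel count times voxel volume regardless (so 4 voxels at 4 mm
    isotropic give exactly 0.256 cm^3).
    """
    count = int(np.count_nonzero(mask))
    voxel_ml = float(np.prod(np.atleast_1d(voxel_size_mm), dtype=np.float64))
    if np.atleast_1d(voxel_size_mm).size == 1:
        voxel_ml = float(voxel_size_mm) ** 3
    mtv_cm3 = count * voxel_ml / 1000.0
    return count >= MIN_MTV_VOXELS, mtv_cm3


def suv_peak(vol: Volume, mask: np.ndarray, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> float:
    """Maximum over in-mask centers of the mean SUV in a ~1 cm^3 sphere.

    Sphere membership is by the voxel-center-in-sphere test; the local mean is
    computed for every voxel by convolution with the normalized sphere kernel
    and maximised over the lesion mask.
    """
    offs = _ball_offsets(radius_mm, vol.voxel_size_mm)
    kshape = tuple(2 * int(math.floor(radius_mm / s)) + 1 for s in vol.voxel_size_mm)
    kernel = np.zeros(kshape, dtype=np.float64)
    center = tuple(s // 2 for s in kshape)
    kernel[tuple((offs + center).T)] = 1.0
    kernel /= kernel.sum()
    local_mean = ndimage.convolve(vol.data.astype(np.float64), kernel, mode="reflect")
    return float(local_mean[mask].max())


def _centroid_mm(mask: np.ndarray, spacing) -> tuple[float, float, float]:
    idx = np.argwhere(mask)
    c = (idx.mean(axis=0) + 0.5) * np.asarray(spacing)
    return tuple(float(v) for v in c)


def extract_features(vol: Volume, mask: np.ndarray, lesion_id: int = 0) -> LesionFeatureSet:
    """SUV_max / SUV_mean / SUV_peak / MTV / TLG for one segmented lesion."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract features from an empty mask")
    vals = vol.data[mask].astype(np.float64)
    _, mtv_cm3 = mtv_filter(mask, vol.voxel_size_mm)
    suv_mean = float(vals.mean())
    return LesionFeatureSet(
        id=lesion_id,
        suv_max=float(vals.max()),
        suv_mean=suv_mean,
        suv_peak=suv_peak(vol, mask),
        mtv_cm3=mtv_cm3,
        tlg_g=suv_mean * mtv_cm3,
        centroid_mm=_centroid_mm(mask, vol.voxel_size_mm),
    )


def match_and_score(
    candidates: Sequence[Sequence[float]],
    truth: Sequence[Sequence[float]],
    tol_mm: float = 10.0,
    panel: ReaderPanel | None = None,
) -> DetectionOutcome:
    """Greedy nearest-first one-to-one centroid matching.

    A candidate matches a truth lesion when their centroids lie within
    ``tol_mm``; each truth lesion is matched at most once. When a panel is
    given its majority consensus replaces the candidate list. Empty lists give
    NaN for the affected rate, with a warning.
    """
    if panel is not None:
        candidates = panel.consensus()
    cand = [np.asarray(c, dtype=np.float64) for c in candidates]
    tru = [np.asarray(t, dtype=np.float64) for t in truth]
    pairs = sorted(
        (
            (float(np.linalg.norm(c - t)), ci, ti)
            for ci, c in enumerate(cand)
            for ti, t in enumerate(tru)
        ),
    )
    used_c: set[int] = set()
    used_t: set[int] = set()
    matched: list[int] = []
    for d, ci, ti in pairs:
        if d > tol_mm:
            break
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matched.append(ti)
    tp = len(matched)
    fp = len(cand) - tp
    fn = len(tru) - tp
    if tp + fn == 0:
        warnings.warn("no truth lesions: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("no candidates: PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    return DetectionOutcome(tp, fp, fn, sorted(matched), sens, ppv)


def detect_candidates(
    vol: Volume,
    body: np.ndarray,
    z_threshold: float = 4.0,
    smooth_mm: float = 5.0,
    background_mm: float = 24.0,
    min_contrast_suv: float = 0.4,
    min_peak_distance_mm: float = 12.0,
) -> list[tuple[float, float, float]]:
    """Algorithmic lesion-candidate finder emulating a reader.

    The volume is lightly smoothed and a *local* background (a much broader
    median-scale smooth) is subtracted, so focal uptake is judged against the
    surrounding tissue rather than a global level — organs of uniform uptake
    are then not flagged wholesale. Local maxima whose contrast exceeds both
    ``z_threshold`` noise scales (robust MAD estimate over the body) and an
    absolute floor of ``min_contrast_suv`` are reported as candidate
    centroids, with non-maximum suppression at ``min_peak_distance_mm``.
    """
    spacing = vol.voxel_size_mm
    sigma_vox = [smooth_mm / 2.354820045 / s for s in spacing]
    sm = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma_vox)
    # residual noise scale of the smoothed image, over the body
    from .classic_filters import estimate_noise_sigma

    scale = max(estimate_noise_sigma(sm, body), 1e-6)
    size = [max(3, int(round(min_peak_distance_mm / s)) | 1) for s in spacing]
    is_max = sm == ndimage.maximum_filter(sm, size=size, mode="nearest")
    peaks = np.argwhere(is_max & body & (sm > 0.25))
    thr = max(z_threshold * scale, min_contrast_suv)
    half = background_mm / 2.0
    rad = [int(np.ceil(half / s)) for s in spacing]
    cands = []
    for idx in peaks:
        # local background: median in a shell [half/2, half] mm around the peak
        lo = [max(i - r, 0) for i, r in zip(idx, rad)]
        hi = [min(i + r + 1, n) for i, r, n in zip(idx, rad, vol.shape)]
        sub = sm[tuple(slice(a, b) for a, b in zip(lo, hi))]
        grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
        d = np.sqrt(sum(((g - i) * s) ** 2 for g, i, s in zip(grids, idx, spacing)))
        shell = (d >= half / 2) & (d <= half)
        if not shell.any():
            continue
        bg = float(np.median(sub[shell]))
        if sm[tuple(idx)] - bg > thr:
            cands.append(tuple((idx + 0.5) * np.asarray(spacing)))
    return cands


def simulated_reader_panel(
    vol: Volume,
    body: np.ndarray,
    z_thresholds: Sequence[float] = (3.5, 4.0, 4.5),
    k: int = 2,
) -> ReaderPanel:
    """Three synthetic readers realised as three detection thresholds.

    An emulation of a majority-based reading (candidates kept when >= k of
    the simulated readers find them), not a claim of equivalence to
    physicians. Each reader's absolute contrast floor scales with their
    z-threshold so the three operating points genuinely differ.
    """
    readers = [
        detect_candidates(vol, body, z_threshold=z, min_contrast_suv=0.4 * z / 4.0)
        for z in z_thresholds
    ]
    return ReaderPanel(readers, k=k)
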