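"""Paired-volume and ROI image-quality metrics.

Voxel-wise: MSE (g^2/mL^2), SSIM, and the intraclass correlation coefficient
for absolute agreement, ICC(A,1) in McGraw-Wong terms — a two-way model with
voxels as subjects and the two volumes as the paired measurements, so both
decorrelation and systematic bias are penalised.

Regional: SNR (ROI mean / ROI sample SD — the standard uniform-region PET
definition) and SUV_mean, plus their relative differences to a reference in
percent. Voxel-wise metrics are computed inside a body mask by default so the
air background does not dilute them; pass ``mask=False`` for the whole grid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.metrics import structural_similarity

from .volio import LabelMask, Volume, body_mask, check_aligned

__all__ = [
    "mse",
    "ssim",
    "icc_absolute",
    "roi_snr",
    "roi_suv_mean",
    "relative_delta",
    "PairedMetricReport",
    "evaluate_pair",
]

#: fixed SSIM dynamic range in SUV so scores are comparable across volumes
DEFAULT_SSIM_RANGE_SUV = 20.0


def _resolve_mask(ref: Volume, mask) -> np.ndarray | None:
    if mask is None:
        return body_mask(ref)
    if mask is False:
        return None
    if isinstance(mask, LabelMask):
        return mask.labels > 0
    return np.asarray(mask, dtype=bool)


def mse(a: Volume, b: Volume, mask=None) -> float:
    """Mean squared voxel difference in g^2/mL^2 (body mask by default)."""
    check_aligned(a, b)
    m = _resolve_mask(b, mask)
    diff = a.data.astype(np.float64) - b.data.astype(np.float64)
    return float(np.mean(diff[m] ** 2)) if m is not None else float(np.mean(diff**2))


def ssim(
    a: Volume,
    b: Volume,
    mask=None,
    data_range: float = DEFAULT_SSIM_RANGE_SUV,
    win_size: int = 7,
) -> float:
    """Mean local SSIM with a uniform ``win_size``^3 window.

    The dynamic range is fixed (default 0-20 SUV) rather than per-pair, so
    scores are comparable across volumes. With a mask, the mean is taken over
    the masked voxels of the local SSIM map.
    """
    check_aligned(a, b)
    m = _resolve_mask(b, mask)
    score, smap = structural_similarity(
        a.data.astype(np.float64),
        b.data.astype(np.float64),
        data_range=data_range,
        win_size=win_size,
        gaussian_weights=False,
        full=True,
    )
    if m is None:
        return float(score)
    return float(np.mean(smap[m]))


def icc_absolute(a: Volume, b: Volume, mask=None, stride: int = 1) -> float:
    """ICC for absolute agreement, single measures — ICC(A,1).

    Voxels are subjects (n), the two volumes the k=2 measurements. From the
    two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR is the between-voxel, MSC the between-volume and MSE the
    residual mean square. ``stride`` subsamples voxels deterministically for
    speed on large grids. Degenerate (zero total variance) input yields NaN
    with a warning.
    """
    check_aligned(a, b)
    m = _resolve_mask(b, mask)
    x = a.data[m] if m is not None else a.data.ravel()
    y = b.data[m] if m is not None else b.data.ravel()
    if stride > 1:
        x, y = x[::stride], y[::stride]
    if x.size < 2:
        raise ValueError("ICC needs at least 2 voxels in the mask")
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    n, k = x.size, 2
    subj_mean = (x + y) / 2.0
    col_mean = np.array([x.mean(), y.mean()])
    grand = subj_mean.mean()
    ssr = k * np.sum((subj_mean - grand) ** 2)
    ssc = n * np.sum((col_mean - grand) ** 2)
    sst = np.sum((x - grand) ** 2) + np.sum((y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mserr = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mserr + k * (msc - mserr) / n
    if sst == 0 or denom == 0:
        warnings.warn("ICC undefined: zero total variance", stacklevel=2)
        return float("nan")
    return float((msr - mserr) / denom)


def roi_snr(vol: Volume, roi: np.ndarray) -> float:
    """ROI mean divided by ROI sample SD (ddof=1). Constant ROI -> +inf."""
    vals = vol.data[np.asarray(roi, dtype=bool)].astype(np.float64)
    if vals.size == 0:
        raise ValueError("ROI is empty")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sd == 0:
        warnings.warn("degenerate ROI: zero SD, SNR is +inf", stacklevel=2)
        return float("inf")
    return float(vals.mean() / sd)


def roi_suv_mean(vol: Volume, roi: np.ndarray) -> float:
    vals = vol.data[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    return float(vals.mean())


def relative_delta(test: float, ref: float) -> float:
    """Relative difference to the reference in percent: 100*(test-ref)/ref."""
    return 100.0 * (test - ref) / ref


@dataclasses.dataclass
class PairedMetricReport:
    """Voxel-wise and per-ROI metrics for one (test, reference) pair."""

    mse: float
    ssim: float
    icc: float
    rois: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)


def evaluate_pair(
    test: Volume,
    ref: Volume,
    rois: dict[str, np.ndarray] | None = None,
    mask=None,
    ssim_range: float = DEFAULT_SSIM_RANGE_SUV,
) -> PairedMetricReport:
    """Full paired report: MSE/SSIM/ICC plus per-ROI SNR and SUV_mean deltas."""
    report = PairedMetricReport(
        mse=mse(test, ref, mask),
        ssim=ssim(test, ref, mask, data_range=ssim_range),
        icc=icc_absolute(test, ref, mask),
    )
    for name, roi in (rois or {}).items():
        snr_t, snr_r = roi_snr(test, roi), roi_snr(ref, roi)
        suv_t, suv_r = roi_suv_mean(test, roi), roi_suv_mean(ref, roi)
        report.rois[name] = {
            "snr": snr_t,
            "suv_mean": suv_t,
            "delta_snr_pct": relative_delta(snr_t, snr_r),
            "delta_suv_mean_pct": relative_delta(suv_t, suv_r),
        }
    return report
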