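"""Static and dynamic amino-acid PET metrics and PET-guided lesion ROIs.

Implements the standard clinical ¹⁸F-FET read-out: a summed 20-40 min image,
tumor-to-brain ratio (TBR) maps against a healthy-brain reference region,
2D auto-contouring at TBR >= 1.6 for TBR_mean, a 1.6 cm circular ROI on the
hottest slice for TBR_max, a 3D ROI by threshold-connected component, and
time-activity-curve (TAC) metrics: time-to-peak and the 20-50 min late-phase
slope in SUV per hour.  All ratio quantities are invariant to a global
rescaling of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PetStudy",
    "PetDerived",
    "frame_mid_times",
    "sum_frames",
    "compute_background",
    "segment_roi3d",
    "tbr_mean_autocontour",
    "tbr_max_circle",
    "extract_tac",
    "ttp",
    "late_slope",
    "derive_pet_metrics",
]

TBR_THRESHOLD = 1.6
CIRCLE_DIAMETER_MM = 16.0
SPHERE_DIAMETER_MM = 16.0


@dataclass
class PetStudy:
    """Dynamic PET frames with their timing (minutes post-injection)."""

    frames: np.ndarray                  # (x, y, z, frame), SUV
    frame_start: np.ndarray             # minutes
    frame_end: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_start = np.asarray(self.frame_start, dtype=float).ravel()
        self.frame_end = np.asarray(self.frame_end, dtype=float).ravel()
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4D (x, y, z, frame)")
        n = self.frames.shape[-1]
        if self.frame_start.size != n or self.frame_end.size != n:
            raise ValueError("frame timing length does not match frame count")
        if np.any(self.frame_end <= self.frame_start):
            raise ValueError("each frame must have end > start")
        if not np.allclose(self.frame_start[1:], self.frame_end[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def mid_times(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start


def frame_mid_times(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return (np.asarray(starts, float) + np.asarray(ends, float)) / 2.0


@dataclass
class PetDerived:
    """Derived quantities of one study against one reference region."""

    summed_20_40: np.ndarray
    background_suv: float
    tbr_map: np.ndarray
    roi2d: np.ndarray
    roi3d: np.ndarray
    tbr_mean: float
    tbr_max: float
    tac: np.ndarray
    ttp: float
    slope: float
    sphere_center: tuple[int, int, int] = (0, 0, 0)

    def metrics(self) -> dict:
        return {
            "TBR_mean": self.tbr_mean,
            "TBR_max": self.tbr_max,
            "TTP": self.ttp,
            "slope": self.slope,
            "background_suv": self.background_suv,
            "roi3d_voxels": int(self.roi3d.sum()),
        }


def sum_frames(study: PetStudy, window: tuple[float, float] = (20.0, 40.0)) -> np.ndarray:
    """Duration-weighted mean image over frames overlapping ``window``.

    Partial frames contribute proportionally to their overlap with the
    window.
    """
    lo, hi = window
    if lo < study.frame_start[0] - 1e-9 or hi > study.frame_end[-1] + 1e-9:
        raise ValueError(
            f"window {window} not covered by acquisition "
            f"({study.frame_start[0]}-{study.frame_end[-1]} min)"
        )
    overlap = np.clip(
        np.minimum(study.frame_end, hi) - np.maximum(study.frame_start, lo), 0.0, None
    )
    if overlap.sum() <= 0:
        raise ValueError("no frame overlaps the summation window")
    w = overlap / overlap.sum()
    return np.tensordot(study.frames, w, axes=([-1], [0]))


def compute_background(summed: np.ndarray, reference_mask: np.ndarray) -> float:
    """Mean SUV of the healthy-brain reference region."""
    mask = np.asarray(reference_mask, dtype=bool)
    if not mask.any():
        raise ValueError("reference mask is empty")
    return float(np.asarray(summed, float)[mask].mean())


def segment_roi3d(tbr_map: np.ndarray, seed_point: tuple[int, int, int],
                  threshold: float = TBR_THRESHOLD) -> np.ndarray:
    """26-connected component of {TBR >= threshold} containing the seed."""
    tbr_map = np.asarray(tbr_map, dtype=float)
    seed = tuple(int(c) for c in seed_point)
    if tbr_map[seed] < threshold:
        supra = np.argwhere(tbr_map >= threshold)
        if supra.size:
            d = np.linalg.norm(supra - np.asarray(seed), axis=1)
            near = supra[np.argsort(d)[:5]].tolist()
        else:
            near = []
        raise ValueError(
            f"seed voxel {seed} has TBR {tbr_map[seed]:.2f} < {threshold}; "
            f"nearest supra-threshold voxels: {near}"
        )
    labels, _ = ndimage.label(tbr_map >= threshold, structure=np.ones((3, 3, 3)))
    return labels == labels[seed]


def tbr_mean_autocontour(tbr_map: np.ndarray, threshold: float = TBR_THRESHOLD,
                         slice_axis: int = 2,
                         slice_index: int | None = None) -> float:
    """Mean TBR over the 2D auto-contoured lesion.

    The contour is the 8-connected supra-threshold region, in the axial slice
    holding the global TBR maximum, that contains that maximum.
    """
    tbr_map = np.asarray(tbr_map, dtype=float)
    peak = np.unravel_index(np.nanargmax(tbr_map), tbr_map.shape)
    if slice_index is None:
        slice_index = peak[slice_axis]
    sl = np.take(tbr_map, slice_index, axis=slice_axis)
    supra = sl >= threshold
    if not supra.any():
        raise ValueError(f"no voxel reaches TBR {threshold} in slice {slice_index}")
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3)))
    peak2d = tuple(np.delete(np.asarray(peak), slice_axis))
    lab = labels[peak2d]
    if lab == 0:  # peak not in this slice's supra set (explicit slice_index)
        idx2d = np.unravel_index(np.argmax(np.where(supra, sl, -np.inf)), sl.shape)
        lab = labels[idx2d]
    return float(sl[labels == lab].mean())


def _peak_voxel(search: np.ndarray) -> tuple[int, ...]:
    """Voxel of maximal value; ties resolve to the one nearest the tied set's
    centroid (relevant for flat phantom lesions, where any tied voxel is a
    valid 'maximal uptake' location but a central one keeps derived ROIs
    inside the lesion)."""
    m = np.nanmax(search)
    cands = np.argwhere(search >= m - 1e-12 * max(1.0, abs(m)))
    centroid = cands.mean(axis=0)
    return tuple(int(c) for c in cands[np.argmin(((cands - centroid) ** 2).sum(axis=1))])


def _circle_mask_2d(shape2d, center2d, voxel_size2d, diameter_mm=CIRCLE_DIAMETER_MM):
    ii = np.indices(shape2d).astype(float)
    d = (ii - np.asarray(center2d, float).reshape(2, 1, 1)) \
        * np.asarray(voxel_size2d, float).reshape(2, 1, 1)
    return (d**2).sum(axis=0) <= (diameter_mm / 2.0) ** 2


def tbr_max_circle(summed: np.ndarray, background_suv: float,
                   voxel_size: tuple[float, float, float],
                   diameter_mm: float = CIRCLE_DIAMETER_MM,
                   stat: str = "mean",
                   lesion_mask: np.ndarray | None = None,
                   center: tuple[int, int, int] | None = None) -> tuple[float, tuple[int, int, int]]:
    """TBR_max from a 2D circular ROI centered on the hottest voxel.

    A circle of ``diameter_mm`` is placed on the axial slice of the global
    uptake maximum (restricted to ``lesion_mask`` when given, or forced to
    ``center``); its mean SUV (``stat='mean'``, default) or maximum
    (``stat='max'``) is divided by the background SUV.  Returns
    ``(tbr_max, peak_voxel)``.
    """
    if background_suv <= 0:
        raise ValueError("background SUV must be positive")
    summed = np.asarray(summed, dtype=float)
    if center is not None:
        peak = tuple(int(c) for c in center)
    else:
        search = summed if lesion_mask is None else np.where(lesion_mask, summed, -np.inf)
        peak = _peak_voxel(search)
    sl = summed[:, :, peak[2]]
    circle = _circle_mask_2d(sl.shape, peak[:2], voxel_size[:2], diameter_mm)
    # warn if the circle is clipped by the image boundary
    r_vox = np.ceil(diameter_mm / 2.0 / np.asarray(voxel_size[:2]))
    if (np.asarray(peak[:2]) - r_vox < 0).any() or \
       (np.asarray(peak[:2]) + r_vox > np.asarray(sl.shape) - 1).any():
        import warnings
        warnings.warn("circular ROI clipped at the image boundary")
    vals = sl[circle]
    stat_val = float(vals.mean()) if stat == "mean" else float(vals.max())
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    return stat_val / background_suv, tuple(int(c) for c in peak)


def _sphere_mask(shape, center, voxel_size, diameter_mm=SPHERE_DIAMETER_MM):
    ii = np.indices(shape).astype(float)
    d = (ii - np.asarray(center, float).reshape(3, 1, 1, 1)) \
        * np.asarray(voxel_size, float).reshape(3, 1, 1, 1)
    return (d**2).sum(axis=0) <= (diameter_mm / 2.0) ** 2


def extract_tac(study: PetStudy, center: tuple[int, int, int],
                diameter_mm: float = SPHERE_DIAMETER_MM) -> np.ndarray:
    """Per-frame mean SUV in a spherical VOI (default 1.6 cm diameter, ~2 ml).

    Voxels belong to the sphere when their centers fall inside it.
    """
    sphere = _sphere_mask(study.frames.shape[:3], center, study.voxel_size, diameter_mm)
    if not sphere.any():
        raise ValueError("spherical VOI contains no voxel centers")
    return study.frames[sphere].mean(axis=0)


def ttp(tac: np.ndarray, mid_times: np.ndarray) -> float:
    """Time-to-peak: mid-time of the first frame attaining the TAC maximum."""
    tac = np.asarray(tac, dtype=float)
    if tac.size == 0:
        raise ValueError("empty TAC")
    return float(np.asarray(mid_times, float)[int(np.argmax(tac))])


def late_slope(tac: np.ndarray, mid_times: np.ndarray,
               window: tuple[float, float] = (20.0, 50.0)) -> float:
    """OLS slope of SUV vs time over the late-phase frames, in SUV per hour."""
    tac = np.asarray(tac, dtype=float)
    t = np.asarray(mid_times, dtype=float)
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 2:
        raise ValueError("need at least 2 frames in the late phase")
    slope_per_min = np.polyfit(t[sel], tac[sel], 1)[0]
    return float(slope_per_min * 60.0)


def derive_pet_metrics(study: PetStudy, reference_mask: np.ndarray,
                       seed_point: tuple[int, int, int] | None = None,
                       threshold: float = TBR_THRESHOLD,
                       tbr_max_stat: str = "mean",
                       peak_smooth_vox: float = 1.0) -> PetDerived:
    """Full static + dynamic read-out of one study.

    The hottest voxel of the summed 20-40 min image seeds the 3D ROI when no
    ``seed_point`` is given; the TAC sphere is centered on the hottest voxel.
    Peak localization runs on a Gaussian-smoothed copy of the summed image
    (``peak_smooth_vox`` voxels; 0 disables) so a noisy plateau does not pull
    the circle/sphere to the lesion rim; all reported values use the
    original, unsmoothed data.
    """
    summed = sum_frames(study)
    background = compute_background(summed, reference_mask)
    tbr_map = summed / background
    search = ndimage.gaussian_filter(summed, peak_smooth_vox) \
        if peak_smooth_vox > 0 else summed
    peak = _peak_voxel(search)
    tbr_max, peak = tbr_max_circle(summed, background, study.voxel_size,
                                   stat=tbr_max_stat, center=peak)
    if seed_point is None:
        seed_point = peak
    roi3d = segment_roi3d(tbr_map, seed_point, threshold)
    tbr_mean = tbr_mean_autocontour(tbr_map, threshold)
    # roi2d: auto-contour region on the peak slice
    sl_idx = peak[2]
    sl = tbr_map[:, :, sl_idx]
    labels, _ = ndimage.label(sl >= threshold, structure=np.ones((3, 3)))
    roi2d = labels == labels[peak[:2]]
    tac = extract_tac(study, peak)
    mids = study.mid_times
    return PetDerived(
        summed_20_40=summed, background_suv=background, tbr_map=tbr_map,
        roi2d=roi2d, roi3d=roi3d, tbr_mean=tbr_mean, tbr_max=tbr_max,
        tac=tac, ttp=ttp(tac, mids), slope=late_slope(tac, mids),
        sphere_center=peak,
    )
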