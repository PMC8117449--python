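"""Histogram-centile features of diffusion/kurtosis maps inside a PET ROI.

Voxel values of each metric map inside the 3D ROI are truncated to a fixed
physiological range (0.5-3.5 um^2/ms for diffusivity maps, 0.4-1.2 for
kurtosis maps, both ends closed), then summarized by the arithmetic mean and
low-tail centiles (C5, C10) for diffusivities or high-tail centiles
(C90, C95) for kurtoses — 18 variables per patient.  Volume-normalized
relative-frequency histograms (smoothed with a 7-bin moving average spanning
0.14 um^2/ms for diffusivities, 0.04 for kurtoses) are produced for
inspection and plotting; the summary statistics are computed on the raw
truncated voxel values, which keeps them independent of the bin grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dki import DkiMaps

__all__ = [
    "HistogramSpec",
    "RelFreqHistogram",
    "HistogramFeatures",
    "truncate_values",
    "build_histogram",
    "summarize",
    "extract_features",
    "DT_MAP_NAMES",
    "KT_MAP_NAMES",
]

log = logging.getLogger(__name__)

DT_MAP_NAMES = ("md", "rd", "ad")
KT_MAP_NAMES = ("mk", "rk", "ak")


@dataclass
class HistogramSpec:
    """Truncation ranges, smoothing windows, and centile sets.

    Bin widths default to window/7 so the moving average spans exactly 7
    bins (an odd count, keeping the smoother centered).
    """

    dt_range: tuple[float, float] = (0.5, 3.5)     # um^2/ms
    kt_range: tuple[float, float] = (0.4, 1.2)     # unitless
    dt_smooth_window: float = 0.14                 # um^2/ms
    kt_smooth_window: float = 0.04
    bin_width_dt: float | None = None
    bin_width_kt: float | None = None
    centiles_dt: tuple[float, ...] = (5.0, 10.0)
    centiles_kt: tuple[float, ...] = (90.0, 95.0)

    def __post_init__(self) -> None:
        if self.bin_width_dt is None:
            self.bin_width_dt = self.dt_smooth_window / 7.0
        if self.bin_width_kt is None:
            self.bin_width_kt = self.kt_smooth_window / 7.0
        for rng in (self.dt_range, self.kt_range):
            if rng[1] <= rng[0]:
                raise ValueError(f"empty truncation range {rng}")
        for window, width, fam in ((self.dt_smooth_window, self.bin_width_dt, "dt"),
                                   (self.kt_smooth_window, self.bin_width_kt, "kt")):
            nbins = window / width
            if abs(nbins - round(nbins)) > 1e-6 or round(nbins) % 2 == 0:
                raise ValueError(
                    f"{fam} smoothing window must be an odd multiple of the bin width"
                )

    def family_of(self, metric: str) -> str:
        if metric.lower() in DT_MAP_NAMES:
            return "dt"
        if metric.lower() in KT_MAP_NAMES:
            return "kt"
        raise KeyError(f"unknown metric {metric!r}")

    def range_for(self, family: str) -> tuple[float, float]:
        return self.dt_range if family == "dt" else self.kt_range

    def window_bins(self, family: str) -> int:
        if family == "dt":
            return round(self.dt_smooth_window / self.bin_width_dt)
        return round(self.kt_smooth_window / self.bin_width_kt)

    def bin_edges(self, family: str) -> np.ndarray:
        lo, hi = self.range_for(family)
        width = self.bin_width_dt if family == "dt" else self.bin_width_kt
        n = int(np.ceil((hi - lo) / width - 1e-9))
        return lo + width * np.arange(n + 1)

    def centiles_for(self, family: str) -> tuple[float, ...]:
        return self.centiles_dt if family == "dt" else self.centiles_kt


@dataclass
class RelFreqHistogram:
    bin_edges: np.ndarray
    frequencies: np.ndarray          # relative, sum to 1 over in-range bins
    smoothed: np.ndarray             # moving-average smoothed, renormalized

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def truncate_values(values: np.ndarray, rng: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Keep values inside the closed interval; return (kept, n_discarded)."""
    lo, hi = rng
    if hi <= lo:
        raise ValueError(f"invalid truncation range {rng}")
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    keep = values[(values >= lo) & (values <= hi)]
    n_discarded = values.size - keep.size
    if keep.size == 0:
        raise ValueError("all voxel values fall outside the truncation range")
    return keep, n_discarded


def build_histogram(values: np.ndarray, spec: HistogramSpec, family: str) -> RelFreqHistogram:
    """Volume-normalized relative-frequency histogram with moving-average
    smoothing over the family's window."""
    if family not in ("dt", "kt"):
        raise ValueError("family must be 'dt' or 'kt'")
    kept, _ = truncate_values(values, spec.range_for(family))
    edges = spec.bin_edges(family)
    counts, _ = np.histogram(kept, bins=edges)
    freq = counts / counts.sum()
    w = spec.window_bins(family)
    kernel = np.ones(w) / w
    smoothed = np.convolve(freq, kernel, mode="same")
    s = smoothed.sum()
    if s > 0:
        smoothed = smoothed / s
    return RelFreqHistogram(bin_edges=edges, frequencies=freq, smoothed=smoothed)


def summarize(values: np.ndarray, spec: HistogramSpec, family: str) -> dict[str, float]:
    """Mean and centiles of the truncated voxel values.

    Centiles use the linear-interpolation quantile convention (inclusive
    closest ranks, numpy's default).
    """
    kept, _ = truncate_values(values, spec.range_for(family))
    out = {"mean": float(kept.mean())}
    for p in spec.centiles_for(family):
        out[f"C{int(p)}"] = float(np.percentile(kept, p))
    return out


@dataclass
class HistogramFeatures:
    """The 18-variable diffusion/kurtosis record for one patient."""

    values: dict[str, float]
    roi_volume_ml: float
    n_voxels_used: dict[str, int] = field(default_factory=dict)
    n_discarded: dict[str, int] = field(default_factory=dict)

    FEATURE_ORDER = tuple(
        [f"{m.upper()}_{s}" for m in DT_MAP_NAMES for s in ("mean", "C5", "C10")]
        + [f"{m.upper()}_{s}" for m in KT_MAP_NAMES for s in ("mean", "C90", "C95")]
    )

    def as_row(self) -> dict[str, float]:
        return {name: self.values.get(name, np.nan) for name in self.FEATURE_ORDER}


def extract_features(maps: DkiMaps, roi3d: np.ndarray,
                     spec: HistogramSpec | None = None) -> HistogramFeatures:
    """Truncate-and-summarize every metric map inside the 3D ROI.

    Metrics with no in-range voxels are recorded as missing (NaN) and
    logged, not raised.
    """
    spec = spec or HistogramSpec()
    roi = np.asarray(roi3d, dtype=bool)
    if roi.shape != maps.md.shape:
        raise ValueError("ROI grid does not match the metric maps")
    if not roi.any():
        raise ValueError("3D ROI is empty")
    voxel_ml = float(np.prod(maps.voxel_size)) / 1000.0
    values: dict[str, float] = {}
    n_used: dict[str, int] = {}
    n_disc: dict[str, int] = {}
    for metric in DT_MAP_NAMES + KT_MAP_NAMES:
        family = spec.family_of(metric)
        vox = maps.metric(metric)[roi]
        try:
            kept, discarded = truncate_values(vox, spec.range_for(family))
        except ValueError:
            log.warning("metric %s has no in-range voxels in the ROI; features set to NaN",
                        metric.upper())
            for s in ("mean",) + tuple(f"C{int(p)}" for p in spec.centiles_for(family)):
                values[f"{metric.upper()}_{s}"] = float("nan")
            n_used[metric.upper()] = 0
            continue
        stats = summarize(kept, spec, family)
        for s, v in stats.items():
            values[f"{metric.upper()}_{s}"] = v
        n_used[metric.upper()] = int(kept.size)
        n_disc[metric.upper()] = int(discarded)
    return HistogramFeatures(values=values, roi_volume_ml=float(roi.sum()) * voxel_ml,
                             n_voxels_used=n_used, n_discarded=n_disc)
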