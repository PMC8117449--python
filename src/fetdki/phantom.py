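"""Image-level phantoms: multi-shell DWI and dynamic amino-acid PET.

A virtual patient is a rectangular grid holding an ellipsoidal "brain" of
white-matter-like tissue and a spherical lesion.  The DWI signal is generated
from the kurtosis forward model (see :mod:`fetdki.dki`) with Rician noise;
the PET study is a 16-frame dynamic volume (5x1, 5x3, 6x5 min frames over
50 min) whose lesion time-activity curve is calibrated, by construction, to
a requested time-to-peak, late-phase slope, and 20-40 min tumor-to-brain
ratio.  Ground-truth parameter maps are returned alongside the noisy data so
the whole downstream pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dki
from .dki import DkiMaps, DwiDataset, FitReport

__all__ = [
    "PhantomConfig",
    "default_frame_schedule",
    "default_acquisition",
    "simulate_dwi_phantom",
    "simulate_pet_phantom",
    "PetStudy",
]

from .pet import PetStudy, frame_mid_times

# group-median lesion targets from the reference cohort (MD/MK histogram
# means; TBR_max, TTP, late slope)
_GROUP_DEFAULTS = {
    "TPR": {"md": 1.32, "mk": 0.61, "tbr": 3.30, "ttp": 27.5, "slope": 0.25},
    "TRC": {"md": 1.54, "mk": 0.50, "tbr": 2.50, "ttp": 37.5, "slope": 0.42},
}


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """(start, end) minutes of the 16-frame dynamic protocol (5x1, 5x3, 6x5)."""
    durations = np.array([1.0] * 5 + [3.0] * 5 + [5.0] * 6)
    ends = np.cumsum(durations)
    return ends - durations, ends


def default_acquisition(n_dirs: int = 30,
                        shells: tuple[float, ...] = (1000.0, 2500.0),
                        n_b0: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Two-shell, 30-direction b-table (b in s/mm^2, unit bvecs as rows)."""
    dirs = dki.fibonacci_sphere(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0)] + [np.full(n_dirs, b) for b in shells])
    bvecs = np.vstack([np.zeros((n_b0, 3))] + [dirs for _ in shells])
    return bvals, bvecs


@dataclass
class TacShape:
    ttp_minutes: float
    late_slope_suv_per_h: float


@dataclass
class PhantomConfig:
    """Geometry, tissue targets, and noise of one virtual patient."""

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    lesion_center: tuple[int, int, int] | None = None          # voxel indices
    lesion_radius: float = 10.0                                # mm
    group: str = "TPR"
    wm_tensor_eigenvalues: tuple[float, float, float] = (1.7, 0.4, 0.4)  # um^2/ms
    wm_kurtosis: float = 0.9
    lesion_md_target: float | None = None   # um^2/ms; default = group median
    lesion_mk_target: float | None = None
    pet_background_suv: float = 1.0
    lesion_tbr_target: float | None = None
    tac_shape: TacShape | None = None
    s0: float = 1000.0
    noise_sigma: float = 0.0                # DWI complex-Gaussian sigma
    pet_noise_sigma: float = 0.0            # PET additive Gaussian sigma (SUV)
    seed: int = 0
    bvals: np.ndarray = field(default_factory=lambda: default_acquisition()[0])
    bvecs: np.ndarray = field(default_factory=lambda: default_acquisition()[1])

    def __post_init__(self) -> None:
        if self.group not in _GROUP_DEFAULTS:
            raise ValueError(f"group must be one of {sorted(_GROUP_DEFAULTS)}")
        g = _GROUP_DEFAULTS[self.group]
        if self.lesion_md_target is None:
            self.lesion_md_target = g["md"]
        if self.lesion_mk_target is None:
            self.lesion_mk_target = g["mk"]
        if self.lesion_tbr_target is None:
            self.lesion_tbr_target = g["tbr"]
        if self.tac_shape is None:
            self.tac_shape = TacShape(g["ttp"], g["slope"])
        if self.lesion_center is None:
            self.lesion_center = tuple(int(s // 2) for s in self.grid_shape)
        for d, name in ((self.lesion_md_target, "lesion_md_target"),):
            if not (0.0 < d <= 3.5):
                raise ValueError(f"{name} must lie in (0, 3.5] um^2/ms")
        for k, name in ((self.lesion_mk_target, "lesion_mk_target"),
                        (self.wm_kurtosis, "wm_kurtosis")):
            if not (0.0 < k < 3.0):
                raise ValueError(f"{name} must lie in (0, 3)")
        # lesion sphere must fit inside the grid
        c = np.asarray(self.lesion_center, dtype=float)
        vs = np.asarray(self.voxel_size, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        r_vox = self.lesion_radius / vs
        if np.any(c - r_vox < 0) or np.any(c + r_vox > shape - 1):
            raise ValueError("lesion sphere does not fit inside the grid")


def _masks(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(brain, lesion, background) boolean volumes."""
    shape = config.grid_shape
    vs = np.asarray(config.voxel_size, dtype=float)
    ii = np.indices(shape).astype(float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = (np.asarray(shape, dtype=float) / 2.0 - 1.5)
    rel = (ii - center.reshape(3, 1, 1, 1)) / semi.reshape(3, 1, 1, 1)
    brain = (rel**2).sum(axis=0) <= 1.0
    lc = np.asarray(config.lesion_center, dtype=float)
    d_mm = (ii - lc.reshape(3, 1, 1, 1)) * vs.reshape(3, 1, 1, 1)
    lesion = (d_mm**2).sum(axis=0) <= config.lesion_radius**2
    lesion &= brain
    background = ~brain
    return brain, lesion, background


def _tissue_parameters(config: PhantomConfig):
    """Ground-truth (d6, w15-scaled) for white matter and lesion."""
    Dwm = np.diag(config.wm_tensor_eigenvalues)
    w_wm = dki.constant_kurtosis_tensor(Dwm, config.wm_kurtosis)
    Dles = np.eye(3) * config.lesion_md_target
    w_les = dki.constant_kurtosis_tensor(Dles, config.lesion_mk_target)
    return (Dwm, w_wm), (Dles, w_les)


def simulate_dwi_phantom(config: PhantomConfig) -> tuple[DwiDataset, DkiMaps]:
    """Forward-simulate a multi-shell DWI phantom plus ground-truth maps.

    The per-voxel noiseless signal follows
    ``ln S = ln S0 - b n'Dn + (b^2/6) MD^2 W(n)``; Rician noise of width
    ``noise_sigma`` is then applied as the magnitude of a complex Gaussian.
    Identical config and seed give bit-identical output.
    """
    b_max = float(np.max(config.bvals))
    if b_max > 2500.0:
        warnings.warn(
            f"b = {b_max:.0f} s/mm^2 exceeds the validated range of the "
            "kurtosis expansion (2500 s/mm^2); interpret fits with care"
        )
    brain, lesion, background = _masks(config)
    (Dwm, w_wm), (Dles, w_les) = _tissue_parameters(config)
    X = dki.build_design_matrix(config.bvals, config.bvecs)
    n_meas = len(config.bvals)

    def signal_for(D, w15):
        md = float(np.trace(D) / 3.0)
        beta = np.concatenate([[np.log(config.s0)], dki.matrix_to_dt6(D), md**2 * w15])
        return np.exp(X @ beta)

    sig_wm = signal_for(Dwm, w_wm)
    sig_les = signal_for(Dles, w_les)
    signal = np.zeros(config.grid_shape + (n_meas,))
    signal[brain] = sig_wm
    signal[lesion] = sig_les
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        re = signal + rng.normal(0.0, config.noise_sigma, signal.shape)
        im = rng.normal(0.0, config.noise_sigma, signal.shape)
        signal = np.sqrt(re**2 + im**2)
    dataset = DwiDataset(signal=signal, bvals=config.bvals, bvecs=config.bvecs,
                         voxel_size=config.voxel_size, brain_mask=brain)

    # ground-truth metric maps
    shape = config.grid_shape
    truth = {m: np.full(shape, np.nan) for m in DkiMaps._METRICS}
    for mask, (D, w15), k in ((brain & ~lesion, (Dwm, w_wm), config.wm_kurtosis),
                              (lesion, (Dles, w_les), None)):
        md, ad, rd = dki.compute_dt_metrics(D)
        kval = k if k is not None else config.lesion_mk_target
        for name, val in (("md", md), ("ad", ad), ("rd", rd),
                          ("mk", kval), ("rk", kval), ("ak", kval)):
            truth[name][mask] = val
    maps = DkiMaps(**truth, mask=brain.copy(), voxel_size=config.voxel_size,
                   report=FitReport(n_voxels=int(brain.sum())))
    return dataset, maps


# --- dynamic PET --------------------------------------------------------------


def _lesion_tac(config: PhantomConfig,
                starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Frame-value TAC meeting the TTP / late-slope / 20-40 min TBR contract.

    Late frames (mid-times in [20, 50] min) sit on a line of the requested
    slope plus a peak perturbation orthogonal, in the least-squares sense, to
    {1, t}, so the OLS late slope is exact; the perturbation peaks at the TTP
    frame.  Early frames follow a gamma-variate-like rise below the peak.
    """
    mids = (starts + ends) / 2.0
    late = (mids >= 20.0) & (mids <= 50.0)
    t = mids[late]
    ttp = config.tac_shape.ttp_minutes
    slope_per_min = config.tac_shape.late_slope_suv_per_h / 60.0
    target_mean = config.lesion_tbr_target * config.pet_background_suv

    # frames overlapping the 20-40 min summation window, overlap-weighted
    w_overlap = np.clip(np.minimum(ends, 40.0) - np.maximum(starts, 20.0), 0.0, None)
    w_late = w_overlap[late]

    base = slope_per_min * (t - t.mean())
    k = int(np.argmin(np.abs(t - ttp)))
    if abs(t[k] - ttp) > 1e-9:
        raise ValueError(
            f"requested TTP {ttp} min is not a frame mid-time of the schedule"
        )
    # peak bump orthogonal to {1, t} -> leaves the OLS slope untouched
    A = np.stack([np.ones_like(t), t], axis=1)
    e = np.zeros_like(t)
    e[k] = 1.0
    u = e - A @ np.linalg.lstsq(A, e, rcond=None)[0]
    u /= u[k]
    # bump height: at least a quarter of the plateau level, and large enough
    # that the TTP frame strictly dominates every other late frame
    margin = 0.02 * target_mean
    need = 0.0
    for i in range(t.size):
        if i == k:
            continue
        gap = 1.0 - u[i]
        if gap <= 1e-9:
            raise RuntimeError("degenerate bump profile")
        need = max(need, (slope_per_min * (t[i] - t[k]) + margin) / gap)
    delta = max(0.25 * target_mean, need)
    y = base + delta * u
    # anchor the overlap-weighted 20-40 min mean at the TBR target
    a = target_mean - float((w_late * y).sum() / w_late.sum())
    y = y + a

    tac = np.empty_like(mids)
    tac[late] = y
    peak_val = y[k]
    early_t = mids[~late]
    alpha = 3.0
    rise = (early_t / ttp) ** alpha * np.exp(alpha * (1.0 - early_t / ttp))
    tac[~late] = 0.9 * min(peak_val, y[0]) * rise / max(rise.max(), (t[0] / ttp) ** alpha * np.exp(alpha * (1 - t[0] / ttp)))
    if int(np.argmax(tac)) != int(np.flatnonzero(late)[k]):
        raise RuntimeError("TAC construction failed to peak at the requested frame")
    return tac


def simulate_pet_phantom(config: PhantomConfig) -> PetStudy:
    """16-frame dynamic PET phantom with a calibrated lesion TAC.

    Background brain activity is flat at ``pet_background_suv``; outside the
    head activity is zero.  Optional additive Gaussian noise per frame.
    """
    starts, ends = default_frame_schedule()
    if not np.isclose(ends[-1], 50.0):
        raise ValueError("frame schedule must span 0-50 minutes")
    brain, lesion, _ = _masks(config)
    tac = _lesion_tac(config, starts, ends)
    frames = np.zeros(config.grid_shape + (len(starts),))
    frames[brain] = config.pet_background_suv
    frames[lesion] = tac
    if config.pet_noise_sigma > 0:
        rng = np.random.default_rng(config.seed + 1)
        frames = frames + rng.normal(0.0, config.pet_noise_sigma, frames.shape)
    return PetStudy(frames=frames, frame_start=starts, frame_end=ends,
                    voxel_size=config.voxel_size)


def phantom_reference_mask(config: PhantomConfig) -> np.ndarray:
    """Contralateral healthy-brain mask for background SUV estimation.

    Mirrors the lesion across the mid-sagittal (x) plane and takes brain
    voxels at least one lesion radius away from the lesion itself.
    """
    brain, lesion, _ = _masks(config)
    shape = config.grid_shape
    vs = np.asarray(config.voxel_size, dtype=float)
    lc = np.asarray(config.lesion_center, dtype=float)
    mirror = lc.copy()
    mirror[0] = (shape[0] - 1) - lc[0]
    if abs(mirror[0] - lc[0]) < 2 * config.lesion_radius / vs[0]:
        # central lesion: use a slab near the x boundary of the brain
        mirror[0] = lc[0] / 2.0
    ii = np.indices(shape).astype(float)
    d_mm = (ii - mirror.reshape(3, 1, 1, 1)) * vs.reshape(3, 1, 1, 1)
    ref = ((d_mm**2).sum(axis=0) <= config.lesion_radius**2) & brain & ~lesion
    if not ref.any():
        raise RuntimeError("failed to construct a reference mask for this geometry")
    return ref
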