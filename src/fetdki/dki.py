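"""Diffusion kurtosis tensor estimation from multi-shell DWI.

The signal model is the cumulant expansion of the diffusion-weighted signal

    ln S(b, n) = ln S0 - b * n'Dn + (b^2 / 6) * MD^2 * W(n),

with ``D`` the 3x3 diffusion tensor (units um^2/ms once b is expressed in
ms/um^2), ``W`` the fully symmetric rank-4 kurtosis tensor (15 unique
elements) and ``W(n) = sum_ijkl n_i n_j n_k n_l W_ijkl``.  The apparent
(directional) kurtosis is

    K(n) = (MD / n'Dn)^2 * W(n),

and MK/RK/AK are directional averages of K: over the whole sphere, over the
plane perpendicular to the principal diffusion eigenvector, and along that
eigenvector, respectively.

Unit convention: the public API accepts b-values in s/mm^2 (as stored in FSL
``.bval`` files); internally b is converted to ms/um^2 (b=1000 s/mm^2 -> 1.0)
so that diffusivities come out in um^2/ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DwiDataset",
    "DkiVoxelFit",
    "DkiMaps",
    "FitReport",
    "estimate_background_sigma",
    "rician_bias_correct",
    "build_design_matrix",
    "fit_dki_voxel",
    "fit_dki_volume",
    "compute_dt_metrics",
    "compute_kt_metrics",
    "fibonacci_sphere",
    "dt6_to_matrix",
    "matrix_to_dt6",
    "kt15_to_tensor",
    "tensor_to_kt15",
    "constant_kurtosis_tensor",
    "apparent_kurtosis",
]

# --- tensor index bookkeeping -------------------------------------------------

# D stored as [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]; quadratic form uses doubled
# off-diagonal coefficients.
_DT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_DT_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

# W stored as the 15 unique elements of a fully symmetric rank-4 tensor, in
# the order below, with the multinomial multiplicity of each index pattern.
_KT_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2),
    (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_KT_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

KURTOSIS_CLIP = (0.0, 3.0)  # directional apparent kurtosis kept physical

S_PER_MM2_TO_MS_PER_UM2 = 1.0 / 1000.0


def dt6_to_matrix(d6: np.ndarray) -> np.ndarray:
    """Expand 6-vector(s) ``[Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`` to 3x3 matrices."""
    d6 = np.asarray(d6, dtype=float)
    out = np.zeros(d6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_DT_IDX):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out


def matrix_to_dt6(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    return np.stack([D[..., i, j] for (i, j) in _DT_IDX], axis=-1)


def kt15_to_tensor(w15: np.ndarray) -> np.ndarray:
    """Expand unique elements to the full symmetric 3x3x3x3 tensor."""
    from itertools import permutations

    w15 = np.asarray(w15, dtype=float)
    W = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for k, idx in enumerate(_KT_IDX):
        for perm in set(permutations(idx)):
            W[(...,) + perm] = w15[..., k]
    return W


def tensor_to_kt15(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    return np.stack([W[(...,) + idx] for idx in _KT_IDX], axis=-1)


def _quadratic_design(dirs: np.ndarray) -> np.ndarray:
    """Rows c2(n) with c2(n) @ d6 = n'Dn."""
    n = np.asarray(dirs, dtype=float)
    cols = [_DT_MULT[k] * n[..., i] * n[..., j] for k, (i, j) in enumerate(_DT_IDX)]
    return np.stack(cols, axis=-1)


def _quartic_design(dirs: np.ndarray) -> np.ndarray:
    """Rows c4(n) with c4(n) @ w15 = sum_ijkl n_i n_j n_k n_l W_ijkl."""
    n = np.asarray(dirs, dtype=float)
    cols = [
        _KT_MULT[k] * n[..., i] * n[..., j] * n[..., kk] * n[..., ll]
        for k, (i, j, kk, ll) in enumerate(_KT_IDX)
    ]
    return np.stack(cols, axis=-1)


def constant_kurtosis_tensor(D: np.ndarray, kurtosis: float) -> np.ndarray:
    """Kurtosis tensor (15-vector) with K(n) = ``kurtosis`` in every direction.

    Uses W = K * sym(D (x) D) / MD^2, whose quartic form is K * (n'Dn)^2 / MD^2,
    so the apparent kurtosis is direction independent.  For isotropic D this
    reduces to the usual isotropic kurtosis tensor.
    """
    D = np.asarray(D, dtype=float)
    md = np.trace(D) / 3.0
    if md <= 0:
        raise ValueError("constant_kurtosis_tensor requires MD > 0")
    T = np.einsum("ij,kl->ijkl", D, D)
    # symmetrize over the three distinct pairings
    T = (
        np.einsum("ij,kl->ijkl", D, D)
        + np.einsum("ik,jl->ijkl", D, D)
        + np.einsum("il,jk->ijkl", D, D)
    ) / 3.0
    return tensor_to_kt15(kurtosis * T / md**2)


_MK_QUADRATURE_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def sphere_quadrature(n_polar: int = 24, n_azimuth: int = 48) -> tuple[np.ndarray, np.ndarray]:
    """Spherical quadrature (directions, weights) for directional averages.

    Gauss-Legendre nodes in cos(theta) crossed with a uniform azimuthal grid;
    for the smooth directional-kurtosis integrand this converges to machine
    precision well below the default order, and the rule is exactly
    rotation-consistent in azimuth.
    """
    key = (n_polar, n_azimuth)
    if key not in _MK_QUADRATURE_CACHE:
        z, wz = np.polynomial.legendre.leggauss(n_polar)
        phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
        Z, PHI = np.meshgrid(z, phi, indexing="ij")
        r = np.sqrt(1.0 - Z**2)
        dirs = np.stack([r * np.cos(PHI), r * np.sin(PHI), Z], axis=-1).reshape(-1, 3)
        w = np.repeat(wz, n_azimuth) / (2.0 * n_azimuth)
        _MK_QUADRATURE_CACHE[key] = (dirs, w)
    return _MK_QUADRATURE_CACHE[key]


def fibonacci_sphere(n: int = 500) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# --- data containers ----------------------------------------------------------


@dataclass
class DwiDataset:
    """4D diffusion-weighted signal plus its acquisition table.

    ``bvals`` are in s/mm^2, ``bvecs`` are unit 3-vectors (one per
    measurement, rows), ``voxel_size`` in mm.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, measurement)")
        n = self.signal.shape[-1]
        if self.bvals.shape[0] != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"acquisition table ({self.bvals.shape[0]} bvals, "
                f"{self.bvecs.shape} bvecs) does not match {n} measurements"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = (self.bvals > 0) & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise ValueError(
                f"non-unit gradient directions at measurements {np.flatnonzero(bad).tolist()}"
            )
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.signal.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask shape does not match signal grid")
        shells = np.unique(np.round(self.bvals[self.bvals > 0]))
        if shells.size < 2:
            raise ValueError("kurtosis estimation needs at least 2 nonzero b-shells")

    @property
    def n_measurements(self) -> int:
        return self.signal.shape[-1]


@dataclass
class DkiVoxelFit:
    """Single-voxel fit result (tensors in internal units)."""

    s0: float
    d6: np.ndarray           # diffusion tensor, um^2/ms
    w15: np.ndarray          # kurtosis tensor, unitless
    fit_residual: float
    converged: bool
    degenerate: bool = False

    @property
    def D(self) -> np.ndarray:
        return dt6_to_matrix(self.d6)

    @property
    def W(self) -> np.ndarray:
        return kt15_to_tensor(self.w15)


@dataclass
class FitReport:
    n_voxels: int = 0
    n_converged: int = 0
    n_degenerate: int = 0
    n_floored: int = 0

    def as_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "n_converged": self.n_converged,
            "n_degenerate": self.n_degenerate,
            "n_floored": self.n_floored,
        }


@dataclass
class DkiMaps:
    """Voxelwise diffusion / kurtosis metric volumes on the DWI grid."""

    md: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    mk: np.ndarray
    rk: np.ndarray
    ak: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None
    report: FitReport = field(default_factory=FitReport)

    _METRICS = ("md", "rd", "ad", "mk", "rk", "ak")

    def metric(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in self._METRICS:
            raise KeyError(f"unknown metric {name!r}; expected one of {self._METRICS}")
        return getattr(self, name)


# --- noise handling -----------------------------------------------------------


def estimate_background_sigma(signal_volume: np.ndarray, background_mask: np.ndarray) -> float:
    """Estimate the complex-Gaussian noise sigma from background magnitudes.

    In signal-free background the magnitude is Rayleigh(sigma); the maximum-
    likelihood estimator is sigma = sqrt(mean(M^2) / 2).
    """
    mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise ValueError("background mask is empty")
    m = np.asarray(signal_volume, dtype=float)[mask]
    sigma = float(np.sqrt(np.mean(m**2) / 2.0))
    if sigma < 1e-12 * max(1.0, float(np.abs(signal_volume).max(initial=0.0))):
        warnings.warn("background variance is near zero; data may be noise-free")
    return sigma


def rician_bias_correct(signal: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Power-images correction of the Rician magnitude bias.

    Returns ``(corrected, floored)`` where corrected = sqrt(max(M^2 - 2 sigma^2, 0))
    and ``floored`` flags voxels/measurements clipped at zero.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    m = np.asarray(signal, dtype=float)
    power = m**2 - 2.0 * sigma**2
    floored = power < 0
    return np.sqrt(np.clip(power, 0.0, None)), floored


# --- design matrix and fitting ------------------------------------------------


def build_design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Design matrix of the log-linearized model.

    Row m maps the parameter vector ``(ln S0, D_6, V_15)`` — where
    ``V = MD^2 * W`` carries the quartic term's own coefficients — to
    ``ln S_m``.  b is converted to ms/um^2 so D is in um^2/ms.
    """
    bvals = np.asarray(bvals, dtype=float).ravel() * S_PER_MM2_TO_MS_PER_UM2
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvecs must be (n_measurements, 3)")
    c2 = _quadratic_design(bvecs)
    c4 = _quartic_design(bvecs)
    X = np.concatenate(
        [
            np.ones((bvals.size, 1)),
            -bvals[:, None] * c2,
            (bvals[:, None] ** 2 / 6.0) * c4,
        ],
        axis=1,
    )
    b0 = bvals == 0
    X[b0, 1:] = 0.0
    rank = np.linalg.matrix_rank(X)
    if rank < 22:
        raise ValueError(
            f"acquisition scheme is rank deficient (rank {rank} < 22): "
            "need >= 2 nonzero shells and >= 15 non-collinear directions"
        )
    return X


def _wls_fit(log_signal: np.ndarray, X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    Xw = X * weights[:, None]
    beta, *_ = np.linalg.lstsq(Xw, log_signal * weights, rcond=None)
    return beta


def _beta_to_fit(beta: np.ndarray, residual: float, converged: bool) -> DkiVoxelFit:
    s0 = float(np.exp(beta[0]))
    d6 = beta[1:7].copy()
    v15 = beta[7:22]
    # project D to PSD by eigenvalue clipping
    D = dt6_to_matrix(d6)
    vals, vecs = np.linalg.eigh(D)
    if vals.min() < 0:
        vals = np.clip(vals, 0.0, None)
        D = vecs @ np.diag(vals) @ vecs.T
        d6 = matrix_to_dt6(D)
    md = float(vals.mean())
    degenerate = md < 1e-6
    if degenerate:
        w15 = np.zeros(15)
    else:
        w15 = v15 / md**2
    return DkiVoxelFit(
        s0=s0, d6=d6, w15=w15, fit_residual=residual,
        converged=converged, degenerate=degenerate,
    )


def fit_dki_voxel(signal_row: np.ndarray, design: np.ndarray,
                  method: str = "nlls", sigma: float = 0.0) -> DkiVoxelFit:
    """Fit the 22-parameter kurtosis model to one voxel's measurements.

    A weighted linear fit on the log of the (bias-corrected) signal
    initializes (weights = signal, the standard first-order variance
    stabilization); ``method='nlls'`` then refines by nonlinear least
    squares on the exponentiated model.  With ``sigma > 0`` the signal is
    first bias-corrected (power-images estimator) and the NLLS residuals
    carry delta-method weights: the corrected amplitude
    ``sqrt(M^2 - 2 sigma^2)`` has variance ~ (M / corrected)^2 sigma^2, so
    low corrected values are down-weighted accordingly.
    """
    y = np.asarray(signal_row, dtype=float)
    if sigma > 0:
        corrected, _ = rician_bias_correct(y, sigma)
    else:
        corrected = y
    ok = corrected > 0
    if ok.sum() < 22:
        raise ValueError("fewer than 22 positive measurements; cannot fit")
    X = design[ok]
    cy = corrected[ok]
    beta = _wls_fit(np.log(cy), X, weights=cy)
    converged = True
    if method == "nlls":
        w = cy / y[ok] if sigma > 0 else np.ones_like(cy)

        def resid(b):
            return (np.exp(X @ b) - cy) * w

        def jac(b):
            return (np.exp(X @ b) * w)[:, None] * X

        sol = least_squares(resid, beta, jac=jac, method="lm", ftol=1e-8,
                            xtol=1e-8, gtol=1e-8, max_nfev=400)
        beta = sol.x
        converged = bool(sol.status > 0)
        residual = float(np.sqrt(np.mean(sol.fun**2)))
    elif method == "wls":
        residual = float(np.sqrt(np.mean((X @ beta - np.log(cy)) ** 2)))
    else:
        raise ValueError("method must be 'wls' or 'nlls'")
    return _beta_to_fit(beta, residual, converged)


# --- scalar metrics -----------------------------------------------------------


def compute_dt_metrics(D: np.ndarray) -> tuple[float, float, float]:
    """(MD, AD, RD) from a symmetric diffusion tensor.

    Eigenvalues sorted descending: AD = l1, RD = (l2 + l3)/2, MD = mean.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be a symmetric 3x3 tensor")
    vals = np.linalg.eigvalsh(D)[::-1]
    return float(vals.mean()), float(vals[0]), float((vals[1] + vals[2]) / 2.0)


def apparent_kurtosis(d6: np.ndarray, w15: np.ndarray, dirs: np.ndarray,
                      clip: tuple[float, float] | None = KURTOSIS_CLIP) -> np.ndarray:
    """Directional apparent kurtosis K(n) for unit directions ``dirs``."""
    d6 = np.asarray(d6, dtype=float)
    md = (d6[..., 0] + d6[..., 1] + d6[..., 2]) / 3.0
    adc = _quadratic_design(dirs) @ d6
    if np.any(adc <= 0):
        raise ValueError("n'Dn <= 0 along an evaluated direction")
    wn = _quartic_design(dirs) @ np.asarray(w15, dtype=float)
    k = (md / adc) ** 2 * wn
    if clip is not None:
        k = np.clip(k, *clip)
    return k


def _perpendicular_dirs(e1: np.ndarray, n_angles: int = 64) -> np.ndarray:
    # orthonormal completion of e1
    ref = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    return np.outer(np.cos(theta), e2) + np.outer(np.sin(theta), e3)


def compute_kt_metrics(D: np.ndarray, W: np.ndarray,
                       quadrature: tuple[int, int] = (24, 48),
                       n_perp: int = 64) -> tuple[float, float, float]:
    """(MK, RK, AK) by directional averaging of the apparent kurtosis.

    MK integrates K(n) over the sphere with a deterministic product
    quadrature, AK is K along the principal diffusion eigenvector, RK
    averages K over ``n_perp`` equally spaced perpendicular directions.
    """
    D = np.asarray(D, dtype=float)
    if D.shape == (3, 3):
        d6 = matrix_to_dt6(D)
    else:
        d6 = D
    W = np.asarray(W, dtype=float)
    w15 = tensor_to_kt15(W) if W.shape == (3, 3, 3, 3) else W
    dirs, weights = sphere_quadrature(*quadrature)
    mk = float(apparent_kurtosis(d6, w15, dirs) @ weights)
    vals, vecs = np.linalg.eigh(dt6_to_matrix(d6))
    e1 = vecs[:, np.argmax(vals)]
    ak = float(apparent_kurtosis(d6, w15, e1[None, :])[0])
    rk = float(apparent_kurtosis(d6, w15, _perpendicular_dirs(e1, n_perp)).mean())
    return mk, rk, ak


# --- volume-level driver ------------------------------------------------------


def fit_dki_volume(dataset: DwiDataset, method: str = "nlls",
                   rician_correction: bool = True,
                   sigma: float | None = None,
                   background_mask: np.ndarray | None = None) -> DkiMaps:
    """Bias-correct, fit voxelwise, and derive metric maps inside the mask.

    ``sigma`` may be given directly; otherwise it is estimated from
    ``background_mask`` (required when ``rician_correction`` is on and no
    sigma is supplied).
    """
    mask = dataset.brain_mask
    shape = dataset.signal.shape[:3]
    report = FitReport(n_voxels=int(mask.sum()))
    if report.n_voxels == 0:
        warnings.warn("brain mask is empty; returning empty maps")
        nanvol = np.full(shape, np.nan)
        return DkiMaps(*(nanvol.copy() for _ in range(6)),
                       mask=np.zeros(shape, bool),
                       voxel_size=dataset.voxel_size, affine=dataset.affine,
                       report=report)

    signal = dataset.signal
    sigma_used = 0.0
    if rician_correction:
        if sigma is None:
            if background_mask is None:
                raise ValueError(
                    "rician correction needs sigma or a background mask to estimate it"
                )
            sigma = estimate_background_sigma(signal[..., 0], background_mask)
        sigma_used = float(sigma)
        _, floored = rician_bias_correct(signal, sigma_used)
        report.n_floored = int(floored[mask].any(axis=-1).sum())

    X = build_design_matrix(dataset.bvals, dataset.bvecs)
    idx = np.argwhere(mask)
    maps = {m: np.full(shape, np.nan) for m in DkiMaps._METRICS}
    conv_mask = np.zeros(shape, dtype=bool)
    for i, j, k in idx:
        row = signal[i, j, k]
        if np.count_nonzero(row**2 > 2.0 * sigma_used**2) < 22:
            continue
        fit = fit_dki_voxel(row, X, method=method, sigma=sigma_used)
        if not fit.converged:
            continue
        report.n_converged += 1
        if fit.degenerate:
            report.n_degenerate += 1
            md, ad, rd = compute_dt_metrics(fit.D)
            mk = rk = ak = 0.0
        else:
            md, ad, rd = compute_dt_metrics(fit.D)
            mk, rk, ak = compute_kt_metrics(fit.d6, fit.w15)
        maps["md"][i, j, k] = md
        maps["ad"][i, j, k] = ad
        maps["rd"][i, j, k] = rd
        maps["mk"][i, j, k] = mk
        maps["rk"][i, j, k] = rk
        maps["ak"][i, j, k] = ak
        conv_mask[i, j, k] = True
    return DkiMaps(**maps, mask=conv_mask, voxel_size=dataset.voxel_size,
                   affine=dataset.affine, report=report)
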