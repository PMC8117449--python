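"""File formats: NIfTI volumes, FSL bval/bvec tables, frame-timing JSON,
cohort CSV, and metric-map bundles."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import FEATURE_NAMES
from .dki import DkiMaps, DwiDataset, FitReport
from .pet import PetStudy

__all__ = [
    "read_dwi", "write_dwi",
    "read_pet", "write_pet",
    "read_maps", "write_maps",
    "read_mask", "write_mask",
    "read_cohort", "write_cohort",
]


def _load_table(path: Path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(x) for x in line.split()])
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: {err}") from None
    return np.array(rows)


def read_dwi(nifti_path, bval_path, bvec_path, mask_path=None) -> DwiDataset:
    """Load a 4D DWI NIfTI with its FSL-style b-table.

    Accepts bvecs in either FSL dialect (3 rows x N columns, or N rows x 3
    columns); they are normalized to row vectors internally.
    """
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.get_fdata(), dtype=float)
    bvals = _load_table(Path(bval_path)).ravel()
    bvecs = _load_table(Path(bvec_path))
    if bvecs.ndim != 2:
        raise ValueError(f"{bvec_path}: expected a 2D table of gradient directions")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"{bvec_path}: expected 3xN or Nx3 gradients, got {bvecs.shape}")
    n = signal.shape[-1]
    if bvals.size != n or bvecs.shape[0] != n:
        raise ValueError(
            f"measurement count mismatch: volume has {n}, "
            f"{bval_path} has {bvals.size}, {bvec_path} has {bvecs.shape[0]}"
        )
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DwiDataset(signal=signal, bvals=bvals, bvecs=bvecs, voxel_size=vs,
                      brain_mask=mask, affine=img.affine)


def write_dwi(dataset: DwiDataset, out_dir, stem: str = "dwi") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = dataset.affine if dataset.affine is not None else _affine(dataset.voxel_size)
    paths = {
        "nifti": out / f"{stem}.nii.gz",
        "bval": out / f"{stem}.bval",
        "bvec": out / f"{stem}.bvec",
        "mask": out / f"{stem}_mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(dataset.signal.astype(np.float32), affine), paths["nifti"])
    paths["bval"].write_text(" ".join(f"{b:g}" for b in dataset.bvals) + "\n")
    # FSL dialect: 3 rows (x, y, z), one column per measurement
    paths["bvec"].write_text(
        "\n".join(" ".join(f"{v:.8f}" for v in dataset.bvecs[:, ax]) for ax in range(3)) + "\n"
    )
    nib.save(nib.Nifti1Image(dataset.brain_mask.astype(np.uint8), affine), paths["mask"])
    return paths


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def read_pet(nifti_path, timing_path) -> PetStudy:
    """4D PET NIfTI plus a JSON frame-timing sidecar
    (``[{"start_min": ..., "end_min": ...}, ...]``)."""
    img = nib.load(str(nifti_path))
    frames = np.asarray(img.get_fdata(), dtype=float)
    timing = json.loads(Path(timing_path).read_text())
    starts = np.array([f["start_min"] for f in timing], dtype=float)
    ends = np.array([f["end_min"] for f in timing], dtype=float)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetStudy(frames=frames, frame_start=starts, frame_end=ends,
                    voxel_size=vs, affine=img.affine)


def write_pet(study: PetStudy, out_dir, stem: str = "pet") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = study.affine if study.affine is not None else _affine(study.voxel_size)
    nifti = out / f"{stem}.nii.gz"
    timing = out / f"{stem}_frames.json"
    nib.save(nib.Nifti1Image(study.frames.astype(np.float32), affine), nifti)
    timing.write_text(json.dumps(
        [{"start_min": float(s), "end_min": float(e)}
         for s, e in zip(study.frame_start, study.frame_end)], indent=1))
    return {"nifti": nifti, "timing": timing}


def write_maps(maps: DkiMaps, out_dir) -> dict[str, Path]:
    """One NIfTI per metric plus a JSON fit report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else _affine(maps.voxel_size)
    paths = {}
    for name in DkiMaps._METRICS:
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps.metric(name).astype(np.float32), affine), p)
        paths[name] = p
    mask_p = out / "fit_mask.nii.gz"
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), affine), mask_p)
    paths["mask"] = mask_p
    report_p = out / "fit_report.json"
    report_p.write_text(json.dumps(maps.report.as_dict(), indent=1))
    paths["report"] = report_p
    return paths


def read_maps(map_dir) -> DkiMaps:
    d = Path(map_dir)
    vols = {}
    affine = None
    vs = (2.0, 2.0, 2.0)
    for name in DkiMaps._METRICS:
        img = nib.load(str(d / f"{name}.nii.gz"))
        vols[name] = np.asarray(img.get_fdata(), dtype=float)
        affine = img.affine
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = np.asarray(nib.load(str(d / "fit_mask.nii.gz")).get_fdata()) > 0.5
    report = FitReport()
    rp = d / "fit_report.json"
    if rp.exists():
        report = FitReport(**json.loads(rp.read_text()))
    return DkiMaps(**vols, mask=mask, voxel_size=vs, affine=affine, report=report)


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def write_mask(mask: np.ndarray, path, voxel_size=(2.0, 2.0, 2.0), affine=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             affine if affine is not None else _affine(voxel_size)), path)
    return path


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns {sorted(missing)}")
    unknown_groups = set(df["group"].unique()) - {"TPR", "TRC"}
    if unknown_groups:
        raise ValueError(f"unknown group labels {sorted(unknown_groups)}")
    absent = [f for f in FEATURE_NAMES if f not in df.columns]
    if absent:
        raise ValueError(f"cohort CSV lacks feature columns {absent}")
    return df
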