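"""File I/O: NIfTI images, capnograph/regressor CSVs, reports and QC JSON.

NIfTI grids are identified by a token derived from the array dimensions and
voxel size; images must match exactly before any voxelwise combination —
there is no implicit resampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .mapping import BoldImage4D, CvrMap, grid_token
from .protocol import CapnoTrace, Regressor
from .roi import RoiReport, TissueMasks

__all__ = [
    "read_capno_csv", "write_capno_csv",
    "read_regressor_csv", "write_regressor_csv",
    "read_bold_nifti", "write_bold_nifti",
    "read_masks_nifti", "write_masks_nifti",
    "write_cvr_map", "read_cvr_nifti",
    "write_roi_report", "write_qc_json",
    "read_censor_file",
]


# ---------------------------------------------------------------------------
# capnograph / regressor CSV

def write_capno_csv(trace: CapnoTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "pco2_mmHg": trace.pco2_mmHg}).to_csv(
        path, index=False
    )


def read_capno_csv(path: str | Path, sample_rate_hz: float | None = None) -> CapnoTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "pco2_mmHg"):
        if col not in df.columns:
            raise InvalidArgumentError(f"capno CSV must have a '{col}' column")
    t = df["time_s"].to_numpy(float)
    if sample_rate_hz is None:
        if len(t) < 2:
            raise InvalidArgumentError("cannot infer sample rate from one sample")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return CapnoTrace(t, df["pco2_mmHg"].to_numpy(float), sample_rate_hz)


def write_regressor_csv(reg: Regressor, path: str | Path) -> None:
    """One-column CSV plus a JSON sidecar carrying TR, t0 and length."""
    path = Path(path)
    pd.DataFrame({"petco2_mmHg": reg.values_mmHg}).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"tr_s": reg.tr_s, "t0_s": reg.t0_s, "n_volumes": reg.n_volumes}, indent=2
    ))


def read_regressor_csv(path: str | Path, tr_s: float | None = None) -> Regressor:
    path = Path(path)
    df = pd.read_csv(path)
    if "petco2_mmHg" not in df.columns:
        raise InvalidArgumentError("regressor CSV must have a 'petco2_mmHg' column")
    t0 = 0.0
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr_s = meta.get("tr_s", tr_s) if tr_s is None else tr_s
        t0 = meta.get("t0_s", 0.0)
    if tr_s is None:
        raise InvalidArgumentError("tr_s not given and no sidecar JSON found")
    return Regressor(df["petco2_mmHg"].to_numpy(float), tr_s, t0)


# ---------------------------------------------------------------------------
# NIfTI

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    return aff


def write_bold_nifti(bold: BoldImage4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(bold.voxel_size_mm))
    img.header.set_zooms((*bold.voxel_size_mm, bold.tr_s))
    nib.save(img, str(path))


def read_bold_nifti(path: str | Path, tr_s: float | None = None) -> BoldImage4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise InvalidArgumentError(f"expected 4-D BOLD NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()
    vox = tuple(round(float(z), 4) for z in zooms[:3])
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if tr_s is None:
        raise InvalidArgumentError("TR not in NIfTI header; pass tr_s explicitly")
    return BoldImage4D(data, vox, tr_s, grid_token(data.shape, vox))


def write_masks_nifti(masks: TissueMasks, path: str | Path) -> None:
    img = nib.Nifti1Image(masks.to_labels(), _affine(masks.voxel_size_mm))
    nib.save(img, str(path))


def read_masks_nifti(path: str | Path) -> TissueMasks:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    if labels.ndim != 3:
        raise InvalidArgumentError(f"expected 3-D label NIfTI, got shape {labels.shape}")
    vox = tuple(round(float(z), 4) for z in img.header.get_zooms()[:3])
    return TissueMasks.from_labels(labels, vox, grid_token(labels.shape, vox))


def write_cvr_map(cvr: CvrMap, prefix: str | Path, voxel_size_mm) -> dict[str, str]:
    """Write ``<prefix>_cvr.nii.gz``, ``<prefix>_r.nii.gz`` and a QC JSON."""
    prefix = str(prefix)
    aff = _affine(voxel_size_mm)
    paths = {
        "cvr": f"{prefix}_cvr.nii.gz",
        "r": f"{prefix}_r.nii.gz",
        "valid": f"{prefix}_valid.nii.gz",
        "qc": f"{prefix}_qc.json",
    }
    nib.save(nib.Nifti1Image(cvr.slope.astype(np.float32), aff), paths["cvr"])
    nib.save(nib.Nifti1Image(cvr.rvalue.astype(np.float32), aff), paths["r"])
    nib.save(nib.Nifti1Image(cvr.valid.astype(np.uint8), aff), paths["valid"])
    write_qc_json(cvr, paths["qc"])
    return paths


def read_cvr_nifti(prefix: str | Path) -> CvrMap:
    prefix = str(prefix)
    slope_img = nib.load(f"{prefix}_cvr.nii.gz")
    slope = np.asarray(slope_img.dataobj, dtype=float)
    rval = np.asarray(nib.load(f"{prefix}_r.nii.gz").dataobj, dtype=float)
    valid = np.asarray(nib.load(f"{prefix}_valid.nii.gz").dataobj).astype(bool)
    vox = tuple(round(float(z), 4) for z in slope_img.header.get_zooms()[:3])
    qc_path = Path(f"{prefix}_qc.json")
    lag, n_used = 0, 0
    if qc_path.exists():
        meta = json.loads(qc_path.read_text())
        lag = meta.get("lag_volumes", 0)
        n_used = meta.get("n_volumes_used", 0)
    baseline = np.where(valid, np.nan, np.nan)  # baseline signal not serialized
    return CvrMap(slope, rval, valid, baseline, grid_token(slope.shape, vox), lag, n_used)


def write_qc_json(cvr: CvrMap, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "lag_volumes": int(cvr.lag_volumes),
        "n_volumes_used": int(cvr.n_volumes_used),
        "fraction_valid": cvr.fraction_valid,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# reports

def write_roi_report(report: RoiReport, path_csv: str | Path,
                     path_json: str | Path | None = None) -> None:
    d = report.to_dict()
    pd.DataFrame([d]).to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(d, indent=2, sort_keys=True))


def read_censor_file(path: str | Path) -> frozenset[int]:
    """Whitespace/newline-separated 0-based volume indexes to censor."""
    text = Path(path).read_text().split()
    return frozenset(int(tok) for tok in text)
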