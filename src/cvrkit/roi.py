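"""Tissue-wise CVR indexes and tissue volumes from a CVR map and masks.

"Brain CVR" is defined over GM ∪ WM: CSF is excluded from the brain average
because its apparent reactivity is artifactually negative (ventricular blood
vessel dilatation displaces CSF, inverting the BOLD response).  ROI means
are unweighted averages over valid voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidArgumentError
from .mapping import CvrMap, grid_token

__all__ = ["TissueMasks", "RoiReport", "roi_volume", "summarize"]


@dataclass(frozen=True)
class TissueMasks:
    """Boolean GM/WM/CSF/ventricle membership on the BOLD grid.

    GM, WM and CSF are mutually exclusive; the ventricle mask is a subset of
    CSF (ventricular voxels are CSF voxels flagged as intraventricular).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    ventricle: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    grid_id: str = ""

    def __post_init__(self) -> None:
        arrays = {}
        shape = None
        for name in ("gm", "wm", "csf", "ventricle"):
            a = np.asarray(getattr(self, name), dtype=bool)
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise InvalidArgumentError("all tissue masks must share one grid")
            arrays[name] = a
        if len(shape) != 3:
            raise InvalidArgumentError("tissue masks must be 3-D")
        overlap = (
            (arrays["gm"] & arrays["wm"])
            | (arrays["gm"] & arrays["csf"])
            | (arrays["wm"] & arrays["csf"])
        )
        if overlap.any():
            raise InvalidArgumentError("gm/wm/csf masks must be mutually exclusive")
        if (arrays["ventricle"] & ~arrays["csf"]).any():
            raise InvalidArgumentError("ventricle mask must be a subset of csf")
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise InvalidArgumentError("voxel_size_mm must be three positive edges")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        object.__setattr__(self, "voxel_size_mm", vox)
        if not self.grid_id:
            object.__setattr__(self, "grid_id", grid_token(shape, vox))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    @property
    def brain(self) -> np.ndarray:
        """Parenchymal mask: GM ∪ WM (CSF excluded)."""
        return self.gm | self.wm

    @property
    def head(self) -> np.ndarray:
        return self.gm | self.wm | self.csf

    @classmethod
    def from_labels(cls, labels: np.ndarray, voxel_size_mm, grid_id: str = "") -> "TissueMasks":
        """Build masks from an integer-coded volume.

        Coding: 0 background, 1 GM, 2 WM, 3 CSF, 4 ventricle (ventricular
        CSF); label 4 contributes to both csf and ventricle.
        """
        lab = np.asarray(labels)
        return cls(
            gm=lab == 1,
            wm=lab == 2,
            csf=(lab == 3) | (lab == 4),
            ventricle=lab == 4,
            voxel_size_mm=voxel_size_mm,
            grid_id=grid_id,
        )

    def to_labels(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int16)
        lab[self.gm] = 1
        lab[self.wm] = 2
        lab[self.csf] = 3
        lab[self.ventricle] = 4
        return lab


@dataclass(frozen=True)
class RoiReport:
    """Tissue-mean CVR indexes (%/mmHg) and tissue volumes (cm³).

    CVR entries are None when an ROI has no valid voxels; volumes depend
    only on the masks, never on the map contents.
    """

    gm_cvr: float | None
    wm_cvr: float | None
    brain_cvr: float | None
    gm_volume_cm3: float
    wm_volume_cm3: float
    n_valid: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "gm_cvr": self.gm_cvr,
            "wm_cvr": self.wm_cvr,
            "brain_cvr": self.brain_cvr,
            "gm_volume_cm3": self.gm_volume_cm3,
            "wm_volume_cm3": self.wm_volume_cm3,
            "n_valid_gm": self.n_valid.get("gm", 0),
            "n_valid_wm": self.n_valid.get("wm", 0),
            "n_valid_brain": self.n_valid.get("brain", 0),
        }


def roi_volume(mask: np.ndarray, voxel_size_mm) -> float:
    """Volume of a boolean ROI in cm³ (voxel count × voxel volume)."""
    vox = tuple(float(v) for v in voxel_size_mm)
    if len(vox) != 3 or any(v <= 0 for v in vox):
        raise InvalidArgumentError("voxel_size_mm must be three positive edges")
    mm3 = float(np.count_nonzero(np.asarray(mask, dtype=bool))) * vox[0] * vox[1] * vox[2]
    return mm3 / 1000.0


def _roi_mean(cvr: CvrMap, mask: np.ndarray) -> tuple[float | None, int]:
    sel = mask & cvr.valid
    n = int(np.count_nonzero(sel))
    if n == 0:
        return None, 0
    return float(cvr.slope[sel].mean()), n


def summarize(cvr: CvrMap, masks: TissueMasks) -> RoiReport:
    """Tissue-mean CVR over valid voxels plus GM/WM volumes.

    An ROI with zero valid voxels yields a None CVR entry and a warning,
    not an exception.
    """
    if cvr.shape != masks.shape or (
        cvr.grid_id and masks.grid_id and cvr.grid_id != masks.grid_id
    ):
        raise GridMismatchError(
            f"CVR map grid '{cvr.grid_id}' != mask grid '{masks.grid_id}'"
        )
    if not masks.head.any():
        raise InvalidArgumentError("all tissue masks are empty")

    gm_mean, n_gm = _roi_mean(cvr, masks.gm)
    wm_mean, n_wm = _roi_mean(cvr, masks.wm)
    brain_mean, n_brain = _roi_mean(cvr, masks.brain)
    for name, mean in (("GM", gm_mean), ("WM", wm_mean), ("brain", brain_mean)):
        if mean is None:
            warnings.warn(f"{name} ROI has no valid voxels; CVR index omitted", stacklevel=2)

    return RoiReport(
        gm_cvr=gm_mean,
        wm_cvr=wm_mean,
        brain_cvr=brain_mean,
        gm_volume_cm3=roi_volume(masks.gm, masks.voxel_size_mm),
        wm_volume_cm3=roi_volume(masks.wm, masks.voxel_size_mm),
        n_valid={"gm": n_gm, "wm": n_wm, "brain": n_brain},
    )
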