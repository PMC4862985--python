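"""Voxelwise CVR mapping: percent BOLD signal change per mmHg PetCO2.

The measurement model is a straight-line least-squares fit of each voxel's
BOLD time course against the end-tidal CO2 regressor.  With raw OLS slope
``b`` (signal units per mmHg) and baseline signal ``S0`` (mean over
normocapnic volumes), the reported reactivity is

    CVR = 100 * b / S0        [% BOLD per mmHg]

and fit confidence is the Pearson product-moment correlation ``r`` between
the time course and the regressor.  Quality control removes (never
interpolates) the first ``n_discard`` volumes (magnetization equilibration)
and any motion-censored volumes, keeping BOLD and regressor in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidArgumentError, QcError
from .protocol import Regressor

__all__ = [
    "BoldImage4D",
    "QcSpec",
    "CvrMap",
    "apply_qc",
    "fit_voxel",
    "compute_cvr_map",
    "censor_from_motion",
    "grid_token",
]

#: minimum retained volumes for a meaningful fit
MIN_VOLUMES = 10

#: half-width (mmHg) of the window around protocol baseline defining the
#: normocapnic epoch used for the percent-change denominator S0
BASELINE_WINDOW_MMHG = 1.0


def grid_token(shape, voxel_size_mm) -> str:
    """Deterministic token identifying a spatial grid (dims + voxel size)."""
    dims = "x".join(str(int(d)) for d in shape[:3])
    vox = ",".join(f"{float(v):.4f}" for v in voxel_size_mm)
    return f"{dims}@{vox}"


@dataclass(frozen=True)
class BoldImage4D:
    """A 4-D BOLD time series on a regular voxel grid."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    grid_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise InvalidArgumentError("BOLD data must be 4-D (x, y, z, t)")
        if not np.all(np.isfinite(data)):
            raise InvalidArgumentError("BOLD data must be finite")
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise InvalidArgumentError("voxel_size_mm must be three positive edges")
        if self.tr_s <= 0:
            raise InvalidArgumentError("tr_s must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vox)
        if not self.grid_id:
            object.__setattr__(self, "grid_id", grid_token(data.shape, vox))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class QcSpec:
    """Initial-volume discard and motion-volume censoring policy.

    Defaults follow the acquisition convention of discarding the first three
    volumes and allowing at most nine motion-censored volumes.
    """

    n_discard: int = 3
    censor_volumes: frozenset[int] = frozenset()
    max_censor: int = 9

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise InvalidArgumentError("n_discard must be >= 0")
        if self.max_censor < 0:
            raise InvalidArgumentError("max_censor must be >= 0")
        censor = frozenset(int(i) for i in self.censor_volumes)
        if any(i < 0 for i in censor):
            raise InvalidArgumentError("censor indexes must be non-negative")
        object.__setattr__(self, "censor_volumes", censor)


@dataclass(frozen=True)
class CvrMap:
    """Per-voxel CVR slope (%/mmHg), Pearson-r confidence and validity."""

    slope: np.ndarray
    rvalue: np.ndarray
    valid: np.ndarray
    baseline_signal: np.ndarray
    grid_id: str
    lag_volumes: int = 0
    n_volumes_used: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.slope.shape

    @property
    def fraction_valid(self) -> float:
        return float(np.mean(self.valid))


def apply_qc(
    bold: BoldImage4D, regressor: Regressor, qc: QcSpec
) -> tuple[BoldImage4D, Regressor]:
    """Drop discarded and censored volumes from BOLD and regressor together.

    Rows are deleted, never interpolated; the two outputs stay in lockstep.
    """
    t = bold.n_volumes
    if regressor.n_volumes != t:
        raise InvalidArgumentError(
            f"regressor length {regressor.n_volumes} != BOLD volumes {t}"
        )
    if qc.n_discard >= t:
        raise QcError(f"n_discard={qc.n_discard} leaves no volumes out of {t}")
    censor = qc.censor_volumes
    if censor and max(censor) >= t:
        raise QcError("censor index out of range")
    if censor & set(range(qc.n_discard)):
        raise QcError("censor indexes overlap the discarded initial volumes")
    if len(censor) > qc.max_censor:
        raise QcError(f"{len(censor)} censored volumes exceed max_censor={qc.max_censor}")

    keep = np.ones(t, dtype=bool)
    keep[: qc.n_discard] = False
    keep[list(censor)] = False
    if keep.sum() < MIN_VOLUMES:
        raise QcError(f"only {int(keep.sum())} volumes remain after QC (< {MIN_VOLUMES})")

    bold_out = BoldImage4D(
        bold.data[..., keep], bold.voxel_size_mm, bold.tr_s, bold.grid_id
    )
    reg_out = Regressor(regressor.values_mmHg[keep], regressor.tr_s, regressor.t0_s)
    return bold_out, reg_out


def _baseline_epoch(x: np.ndarray, baseline_mmHg: float | None) -> np.ndarray:
    """Boolean mask of normocapnic volumes; falls back to all volumes."""
    base = float(np.min(x)) if baseline_mmHg is None else float(baseline_mmHg)
    mask = np.abs(x - base) <= BASELINE_WINDOW_MMHG
    if not mask.any():
        mask = np.ones_like(mask)
    return mask


def fit_voxel(
    ts: np.ndarray,
    regressor: Regressor | np.ndarray,
    baseline_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS fit of one voxel's time course against the PetCO2 regressor.

    Returns ``(slope, rvalue)`` where slope is in % BOLD per mmHg,
    normalized by the mean signal over ``baseline_mask`` volumes (all
    volumes if None).  A constant time course yields ``(0.0, 0.0)``.
    """
    y = np.asarray(ts, dtype=float)
    x = regressor.values_mmHg if isinstance(regressor, Regressor) else np.asarray(regressor, float)
    if y.shape != x.shape or y.ndim != 1:
        raise InvalidArgumentError("time course and regressor must be 1-D of equal length")
    if len(y) < 3:
        raise InvalidArgumentError("need at least 3 volumes to fit")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise InvalidArgumentError("regressor has zero variance")
    bmask = np.ones(len(y), bool) if baseline_mask is None else np.asarray(baseline_mask, bool)
    s0 = float(y[bmask].mean())
    if s0 == 0.0:
        raise InvalidArgumentError("baseline signal is zero; cannot percent-normalize")
    yc = y - y.mean()
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    b = sxy / sxx
    r = 0.0 if syy == 0.0 else sxy / np.sqrt(sxx * syy)
    return 100.0 * b / s0, r


def _masked_fit(V: np.ndarray, x: np.ndarray, bmask: np.ndarray):
    """Vectorized OLS of every row of V (voxels x time) on x."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    s0 = V[:, bmask].mean(axis=1)
    Vc = V - V.mean(axis=1, keepdims=True)
    sxy = Vc @ xc
    syy = np.einsum("ij,ij->i", Vc, Vc)
    b = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(syy > 0.0, sxy / np.sqrt(sxx * syy), 0.0)
    np.clip(r, -1.0, 1.0, out=r)
    return b, r, s0


def compute_cvr_map(
    bold: BoldImage4D,
    regressor: Regressor,
    qc: QcSpec | None = None,
    analysis_mask: np.ndarray | None = None,
    baseline_mmHg: float | None = None,
    signal_floor: float | None = None,
    lag_search: bool = False,
    lag_window: int = 5,
) -> CvrMap:
    """Fit every in-mask voxel and assemble slope / r / validity maps.

    Parameters
    ----------
    qc : QcSpec or None
        Volume discard/censor policy applied before fitting (None = no QC).
    analysis_mask : bool array or None
        Spatial mask of voxels to fit; out-of-mask voxels are invalid.
    baseline_mmHg : float or None
        Protocol baseline used to locate the normocapnic epoch for the
        percent-change denominator; inferred as the regressor minimum when
        None.
    signal_floor : float or None
        Voxels with baseline signal at or below this are flagged invalid
        (air); default 1e-6 x the in-mask grand mean absolute signal.
    lag_search : bool
        When True, search a global integer-volume lag of BOLD behind PetCO2
        in ``[-lag_window, +lag_window]`` maximizing mean in-mask fit r.
    """
    if qc is not None:
        bold, regressor = apply_qc(bold, regressor, qc)
    spatial = bold.shape[:3]
    if analysis_mask is None:
        mask = np.ones(spatial, dtype=bool)
    else:
        mask = np.asarray(analysis_mask, dtype=bool)
        if mask.shape != spatial:
            raise GridMismatchError(
                f"analysis mask shape {mask.shape} != BOLD grid {spatial}"
            )

    nan = np.full(spatial, np.nan)
    out_invalid = CvrMap(
        nan.copy(), nan.copy(), np.zeros(spatial, bool), nan.copy(),
        bold.grid_id, 0, bold.n_volumes,
    )
    if not mask.any():
        return out_invalid

    x = regressor.values_mmHg
    if float(np.ptp(x)) == 0.0:
        raise InvalidArgumentError("regressor has zero variance")
    V = bold.data[mask]  # (n_voxels, t)
    bmask = _baseline_epoch(x, baseline_mmHg)

    lag = 0
    if lag_search:
        lag = _best_lag(V, x, lag_window)
    if lag > 0:
        Vl, xl = V[:, lag:], x[: len(x) - lag]
    elif lag < 0:
        Vl, xl = V[:, : len(x) + lag], x[-lag:]
    else:
        Vl, xl = V, x
    bmask_l = _baseline_epoch(xl, baseline_mmHg)

    b, r, s0 = _masked_fit(Vl, xl, bmask_l)
    floor = signal_floor
    if floor is None:
        floor = 1e-6 * float(np.mean(np.abs(V)))
    ok = s0 > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ok, 100.0 * b / np.where(ok, s0, 1.0), np.nan)
    rv = np.where(ok, r, np.nan)

    slope_map = np.full(spatial, np.nan)
    r_map = np.full(spatial, np.nan)
    s0_map = np.full(spatial, np.nan)
    valid = np.zeros(spatial, dtype=bool)
    slope_map[mask] = slope
    r_map[mask] = rv
    s0_map[mask] = s0
    valid[mask] = ok
    return CvrMap(slope_map, r_map, valid, s0_map, bold.grid_id, lag, Vl.shape[1])


def _best_lag(V: np.ndarray, x: np.ndarray, lag_window: int) -> int:
    """Global integer-volume lag maximizing mean fit r over voxels."""
    best_lag, best_score = 0, -np.inf
    for lag in range(-lag_window, lag_window + 1):
        if lag > 0:
            Vl, xl = V[:, lag:], x[: len(x) - lag]
        elif lag < 0:
            Vl, xl = V[:, : len(x) + lag], x[-lag:]
        else:
            Vl, xl = V, x
        if len(xl) < MIN_VOLUMES or float(np.ptp(xl)) == 0.0:
            continue
        _, r, _ = _masked_fit(Vl, xl, _baseline_epoch(xl, None))
        score = float(np.mean(r))
        # prefer smaller |lag| on ties so the no-lag default is stable
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and abs(lag) < abs(best_lag)
        ):
            best_lag, best_score = lag, score
    return best_lag


def censor_from_motion(
    motion_params: np.ndarray, fd_threshold_mm: float = 0.9, head_radius_mm: float = 50.0
) -> frozenset[int]:
    """Volumes exceeding a framewise-displacement threshold.

    ``motion_params`` is (t, 6): three translations (mm) and three rotations
    (rad); rotations are converted to arc length on a sphere of
    ``head_radius_mm``.  FD of volume i is the sum of absolute parameter
    differences from volume i-1 (FD of volume 0 is 0).
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise InvalidArgumentError("motion_params must be (t, 6)")
    if fd_threshold_mm <= 0:
        raise InvalidArgumentError("fd_threshold_mm must be positive")
    scaled = mp.copy()
    scaled[:, 3:] *= head_radius_mm
    fd = np.zeros(len(mp))
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return frozenset(int(i) for i in np.nonzero(fd > fd_threshold_mm)[0])
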