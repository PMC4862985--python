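"""Synthetic data: digital 4-D BOLD phantoms and subject cohorts.

Two generators make every pipeline stage testable without patient data:

* :func:`generate_phantom` builds a nested-box head phantom (CSF rim, GM
  shell, WM core, ventricular pocket) whose every voxel follows the linear
  reactivity model ``S(t) = S0 * (1 + (c/100) * (PetCO2(t) - baseline)) +
  drift * t + noise``, returning the ground-truth CVR field ``c`` for
  recovery tests.  The ventricular compartment has negative ``c``: rising
  CO2 dilates ventricular vessels and displaces CSF, so its BOLD time
  course is inversely correlated with PetCO2.
* :func:`generate_cohort` draws subject-level records (SCAT2, SSS, CVR
  indexes, tissue volumes, demographics) from a latent Gaussian copula with
  per-group marginal means/SDs and a target correlation structure, plus
  correlated visit-2 follow-up records for a subset of patients.

The module-level presets encode the healthy-control and mTBI study
conditions (tissue reactivities 0.28 / 0.160 %/mmHg in controls, opposite-
sign SCAT2-CVR correlations between groups, longitudinal GM-volume
decline) so that tests can assert recovery of known quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParamsError, SpecError
from .mapping import BoldImage4D, grid_token
from .protocol import DEFAULT_BASELINE_MMHG, Regressor
from .roi import TissueMasks
from .stats import CohortTable

__all__ = [
    "Compartment",
    "PhantomSpec",
    "CohortGenParams",
    "generate_phantom",
    "generate_cohort",
    "healthy_tissue_compartments",
    "mtbi_tissue_compartments",
    "study_cohort_params",
    "nearest_psd_correlation",
    "effective_correlation",
    "COHORT_VARIABLES",
]


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class Compartment:
    """Generating parameters of one tissue class."""

    true_cvr_pct_per_mmHg: float
    baseline_signal: float
    noise_sd: float = 0.0
    drift_per_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_signal < 0:
            raise SpecError("baseline_signal must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


TISSUES = ("gm", "wm", "csf", "ventricle")


def healthy_tissue_compartments(noise_sd: float = 0.0, drift: float = 0.0):
    """Healthy-control tissue reactivities: GM 0.28, WM 0.160 %/mmHg.

    CSF is weakly reactive and the ventricular pocket is negative
    (CSF-displacement artifact).
    """
    return {
        "gm": Compartment(0.28, 1000.0, noise_sd, drift),
        "wm": Compartment(0.160, 800.0, noise_sd, drift),
        "csf": Compartment(0.05, 600.0, noise_sd, drift),
        "ventricle": Compartment(-0.10, 500.0, noise_sd, drift),
    }


def mtbi_tissue_compartments(noise_sd: float = 0.0, drift: float = 0.0):
    """mTBI tissue reactivities: GM 0.26, WM 0.1472 %/mmHg."""
    return {
        "gm": Compartment(0.26, 1000.0, noise_sd, drift),
        "wm": Compartment(0.1472, 800.0, noise_sd, drift),
        "csf": Compartment(0.05, 600.0, noise_sd, drift),
        "ventricle": Compartment(-0.10, 500.0, noise_sd, drift),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition and compartment parameters of a phantom.

    The head occupies a centered box; within it, nested one-/two-voxel
    shells assign a CSF rim, a GM shell and a WM core, with a small
    ventricular (CSF) pocket at the center.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.6, 3.6, 3.0)
    tr_s: float = 2.0
    n_volumes: int = 255
    baseline_mmHg: float = DEFAULT_BASELINE_MMHG
    compartments: dict = field(default_factory=healthy_tissue_compartments)
    seed: int = 0

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 10 for d in dims[:2]) or dims[2] < 6:
            raise SpecError("grid_dims must be 3 counts, at least (10, 10, 6)")
        if self.n_volumes < 10:
            raise SpecError("n_volumes must be >= 10")
        if set(self.compartments) != set(TISSUES):
            raise SpecError(f"compartments must define exactly {TISSUES}")
        object.__setattr__(self, "grid_dims", dims)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))


def _phantom_labels(dims: tuple[int, int, int]) -> np.ndarray:
    """Integer tissue labels (0 bg, 1 GM, 2 WM, 3 CSF, 4 ventricle).

    Nested boxes: background border, CSF rim, GM shell, WM core, with a
    small ventricular (CSF) pocket carved from the core center.  Margins
    shrink on small grids so every compartment stays non-empty.
    """
    nx, ny, nz = dims
    lab = np.zeros(dims, dtype=np.int16)

    def box(mx: int, mz: int) -> tuple[slice, slice, slice]:
        return (slice(mx, nx - mx), slice(mx, ny - mx), slice(mz, nz - mz))

    mx_wm = min(5, (min(nx, ny) - 2) // 2)
    mz_wm = max(2, min(3, (nz - 2) // 2))
    lab[box(2, 1)] = 3        # head: CSF rim outermost
    lab[box(3, 2)] = 1        # GM shell
    lab[box(mx_wm, mz_wm)] = 2  # WM core
    # ventricular pocket strictly inside the WM core
    core = [(mx_wm, nx - mx_wm), (mx_wm, ny - mx_wm), (mz_wm, nz - mz_wm)]
    half = [min(c, max(1, (b - a) // 2)) for (a, b), c in zip(core, (4, 4, 2))]
    vent = tuple(
        slice(a + (b - a - h) // 2, a + (b - a - h) // 2 + h)
        for (a, b), h in zip(core, half)
    )
    lab[vent] = 4
    if not np.all([np.any(lab == k) for k in (1, 2, 3, 4)]):
        raise SpecError("grid too small: some tissue compartment is empty")
    return lab


def generate_phantom(
    spec: PhantomSpec, regressor: Regressor, seed: int | None = None
) -> tuple[BoldImage4D, TissueMasks, np.ndarray]:
    """Simulate a 4-D BOLD phantom driven by a PetCO2 regressor.

    Returns ``(bold, masks, truth)`` where ``truth`` is the per-voxel
    generating CVR field (%/mmHg; NaN outside the head).  Deterministic for
    a given seed (default: ``spec.seed``).
    """
    if regressor.n_volumes != spec.n_volumes:
        raise InvalidArgumentError(
            f"regressor length {regressor.n_volumes} != spec.n_volumes {spec.n_volumes}"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = _phantom_labels(spec.grid_dims)
    gid = grid_token(spec.grid_dims, spec.voxel_size_mm)
    masks = TissueMasks.from_labels(labels, spec.voxel_size_mm, gid)

    t = spec.n_volumes
    x = regressor.values_mmHg
    dx = x - spec.baseline_mmHg
    vol_idx = np.arange(t, dtype=float)

    data = np.zeros((*spec.grid_dims, t))
    truth = np.full(spec.grid_dims, np.nan)
    tissue_masks = {"gm": masks.gm, "wm": masks.wm,
                    "csf": masks.csf & ~masks.ventricle, "ventricle": masks.ventricle}
    for name, tmask in tissue_masks.items():
        comp: Compartment = spec.compartments[name]
        n_vox = int(tmask.sum())
        base = comp.baseline_signal * (
            1.0 + (comp.true_cvr_pct_per_mmHg / 100.0) * dx
        ) + comp.drift_per_volume * vol_idx
        series = np.tile(base, (n_vox, 1))
        if comp.noise_sd > 0:
            series = series + rng.normal(0.0, comp.noise_sd, series.shape)
        data[tmask] = series
        truth[tmask] = comp.true_cvr_pct_per_mmHg

    bold = BoldImage4D(data, spec.voxel_size_mm, spec.tr_s, gid)
    return bold, masks, truth


# ---------------------------------------------------------------------------
# cohort

#: continuous subject-level variables drawn from the latent copula, in order
COHORT_VARIABLES = (
    "age_years", "scat2", "sss", "gm_cvr", "wm_cvr", "brain_cvr",
    "gm_volume_cm3", "wm_volume_cm3", "petco2_min", "petco2_max",
)

CONTROL_MARGINALS = {
    "age_years": (38.7, 12.6),
    "scat2": (91.5, 5.7),
    "sss": (5.28, 10.2),
    "gm_cvr": (0.28, 0.06),
    "wm_cvr": (0.160, 0.04),
    "brain_cvr": (0.215, 0.04),
    "gm_volume_cm3": (375.2, 40.8),
    "wm_volume_cm3": (417.1, 47.2),
    "petco2_min": (34.94, 3.36),
    "petco2_max": (44.0, 4.04),
}

MTBI_MARGINALS = {
    "age_years": (42.7, 16.3),
    "scat2": (72.76, 10.9),
    "sss": (35.72, 24.8),
    "gm_cvr": (0.26, 0.091),
    "wm_cvr": (0.1472, 0.05),
    "brain_cvr": (0.20, 0.072),
    "gm_volume_cm3": (365.14, 47.4),
    "wm_volume_cm3": (413.83, 48.8),
    "petco2_min": (34.63, 5.03),
    "petco2_max": (44.70, 3.67),
}

# visit-2 marginals for followed mTBI patients (visit-2 WM CVR SD taken as
# 0.040, matching the visit-1 scale); variables not listed keep visit-1
# marginals
MTBI_VISIT2_MARGINALS = {
    "scat2": (77.8, 14.22),
    "wm_cvr": (0.1468, 0.040),
    "gm_cvr": (0.25, 0.074),
    "brain_cvr": (0.20, 0.05),
    "gm_volume_cm3": (351.4, 42.3),
    "wm_volume_cm3": (410.97, 53.9),
}

# target pairwise correlations per group (unspecified pairs default to 0 and
# the completed matrix is projected to the nearest PSD correlation matrix)
CONTROL_CORR = {
    ("age_years", "scat2"): -0.60,
    ("scat2", "wm_cvr"): -0.59,
    ("scat2", "gm_cvr"): -0.56,
    ("scat2", "brain_cvr"): -0.58,
    ("scat2", "gm_volume_cm3"): 0.2945,
}

MTBI_CORR = {
    ("age_years", "scat2"): -0.62,
    ("scat2", "gm_cvr"): 0.40,
    ("scat2", "brain_cvr"): 0.40,
    ("scat2", "gm_volume_cm3"): 0.5215,
    ("wm_cvr", "wm_volume_cm3"): -0.46,
}


@dataclass(frozen=True)
class CohortGenParams:
    """Parameters of the latent-copula cohort generator."""

    n_control: int = 18
    n_mtbi: int = 25
    n_followup: int = 19
    control_marginals: dict = field(default_factory=lambda: dict(CONTROL_MARGINALS))
    mtbi_marginals: dict = field(default_factory=lambda: dict(MTBI_MARGINALS))
    mtbi_visit2_marginals: dict = field(default_factory=lambda: dict(MTBI_VISIT2_MARGINALS))
    control_corr: dict = field(default_factory=lambda: dict(CONTROL_CORR))
    mtbi_corr: dict = field(default_factory=lambda: dict(MTBI_CORR))
    male_fraction_control: float = 11.0 / 18.0
    male_fraction_mtbi: float = 18.0 / 25.0
    exact_sex_counts: bool = True
    #: generic test-retest correlation of visit-2 vs visit-1 latents
    retest_corr: float = 0.7
    #: per-variable overrides; volumetric measures are far more stable than
    #: functional ones, and the observed paired GM-volume decline implies a
    #: retest correlation near 0.95
    retest_overrides: dict = field(
        default_factory=lambda: {"gm_volume_cm3": 0.95, "wm_volume_cm3": 0.95}
    )
    days_first_visit: tuple[float, float] = (63.5, 42.0)
    days_second_visit: tuple[float, float] = (180.0, 38.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_followup > self.n_mtbi:
            raise ParamsError("n_followup cannot exceed n_mtbi")
        if min(self.n_control, self.n_mtbi, self.n_followup) < 0:
            raise ParamsError("cohort sizes must be non-negative")
        for marg in (self.control_marginals, self.mtbi_marginals):
            missing = set(COHORT_VARIABLES) - set(marg)
            if missing:
                raise ParamsError(f"marginals missing variables: {sorted(missing)}")
            if any(sd < 0 for _, sd in marg.values()):
                raise ParamsError("marginal SDs must be >= 0")
        for corr in (self.control_corr, self.mtbi_corr):
            for pair, r in corr.items():
                if abs(r) >= 1.0:
                    raise ParamsError(f"|target correlation| must be < 1 for {pair}")
                if not set(pair) <= set(COHORT_VARIABLES):
                    raise ParamsError(f"unknown variables in correlation pair {pair}")
        for rho in (self.retest_corr, *self.retest_overrides.values()):
            if not -1.0 < rho < 1.0:
                raise ParamsError("retest correlations must be in (-1, 1)")


def study_cohort_params(seed: int = 0, **overrides) -> CohortGenParams:
    """The study preset: 18 controls, 25 mTBI, 19 with follow-up."""
    return CohortGenParams(seed=seed, **overrides)


def nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping followed by re-normalization of the diagonal; exact
    for matrices that are already PSD.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ParamsError("correlation matrix must be square")
    if not np.allclose(c, c.T):
        raise ParamsError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    if vals.min() >= eps:
        return c
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _corr_matrix(pairs: dict) -> np.ndarray:
    k = len(COHORT_VARIABLES)
    idx = {v: i for i, v in enumerate(COHORT_VARIABLES)}
    c = np.eye(k)
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = r
        c[idx[b], idx[a]] = r
    return nearest_psd_correlation(c)


def effective_correlation(params: CohortGenParams, group: str) -> pd.DataFrame:
    """The PSD-projected latent correlation matrix actually sampled from.

    Target pairs with large joint loadings may be attenuated by the
    projection; this is the generator's operative target.
    """
    pairs = params.control_corr if group == "control" else params.mtbi_corr
    c = _corr_matrix(pairs)
    return pd.DataFrame(c, index=COHORT_VARIABLES, columns=COHORT_VARIABLES)


def _sample_latent(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    jitter = 1e-10 * np.eye(len(corr))
    chol = np.linalg.cholesky(corr + jitter)
    return rng.standard_normal((n, len(corr))) @ chol.T


def _sexes(rng, n: int, male_fraction: float, exact: bool) -> np.ndarray:
    if exact:
        n_male = int(round(male_fraction * n))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        return rng.permutation(sexes)
    return np.where(rng.random(n) < male_fraction, "M", "F")


def _records(group, ids, sexes, ages, days, values, visit):
    rows = []
    for i, sid in enumerate(ids):
        row = {
            "subject_id": sid,
            "group": group,
            "visit": visit,
            "age_years": float(ages[i]),
            "sex": sexes[i],
            "days_post_injury": float(days[i]) if days is not None else np.nan,
        }
        for var in COHORT_VARIABLES:
            if var == "age_years":
                continue
            row[var] = float(values[var][i])
        rows.append(row)
    return rows


def generate_cohort(params: CohortGenParams) -> CohortTable:
    """Draw a synthetic cohort with the requested structure.

    Continuous variables come from a latent Gaussian copula whose
    correlation matrix is the PSD projection of the per-group targets;
    marginals are Gaussian with the preset means/SDs (SCAT2 clipped to its
    0-100 range).  Visit-2 records for ``n_followup`` patients are
    generated as ``z2 = rho * z1 + sqrt(1 - rho^2) * e`` on the latent
    scale, with innovations drawn from the same copula, then mapped to the
    visit-2 marginals.
    """
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []

    for group, n, marg, corr_pairs, male_frac in (
        ("control", params.n_control, params.control_marginals,
         params.control_corr, params.male_fraction_control),
        ("mtbi", params.n_mtbi, params.mtbi_marginals,
         params.mtbi_corr, params.male_fraction_mtbi),
    ):
        if n == 0:
            continue
        corr = _corr_matrix(corr_pairs)
        z1 = _sample_latent(rng, corr, n)
        values = {}
        for j, var in enumerate(COHORT_VARIABLES):
            m, s = marg[var]
            values[var] = m + s * z1[:, j]
        values["scat2"] = np.clip(values["scat2"], 0.0, 100.0)
        for var in ("gm_volume_cm3", "wm_volume_cm3"):
            values[var] = np.maximum(values[var], 0.0)
        sexes = _sexes(rng, n, male_frac, params.exact_sex_counts)
        ids = [f"{'CTRL' if group == 'control' else 'MTBI'}{i + 1:02d}" for i in range(n)]
        if group == "mtbi":
            m_d, s_d = params.days_first_visit
            days = np.maximum(rng.normal(m_d, s_d, n), 1.0)
        else:
            days = None
        rows.extend(_records(group, ids, sexes, values["age_years"], days, values, 1))

        if group == "mtbi" and params.n_followup > 0:
            followers = np.sort(rng.choice(n, size=params.n_followup, replace=False))
            e = _sample_latent(rng, corr, params.n_followup)
            v2 = {}
            for j, var in enumerate(COHORT_VARIABLES):
                rho = params.retest_overrides.get(var, params.retest_corr)
                z2 = rho * z1[followers, j] + np.sqrt(1.0 - rho**2) * e[:, j]
                m2, s2 = params.mtbi_visit2_marginals.get(var, marg[var])
                v2[var] = m2 + s2 * z2
            v2["scat2"] = np.clip(v2["scat2"], 0.0, 100.0)
            for var in ("gm_volume_cm3", "wm_volume_cm3"):
                v2[var] = np.maximum(v2[var], 0.0)
            # demographics carry over; follow-up interval redrawn
            v2["age_years"] = values["age_years"][followers]
            m_d2, s_d2 = params.days_second_visit
            days2 = np.maximum(rng.normal(m_d2, s_d2, params.n_followup), 2.0)
            ids2 = [ids[i] for i in followers]
            sexes2 = sexes[followers]
            rows.extend(_records("mtbi", ids2, sexes2, v2["age_years"], days2, v2, 2))

    df = pd.DataFrame(rows)
    return CohortTable(df)
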