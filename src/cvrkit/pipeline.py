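"""End-to-end driver: capnograph → regressor → CVR map → ROI summary →
cohort statistics, with a manifest for reproducibility.

Per imaging subject the stages run in order and their outputs land under
``out_dir``; imaging-derived scalars (tissue CVR indexes, volumes, PetCO2
range) are merged into the cohort table before the statistics preset runs.
Stage failures are wrapped in :class:`~cvrkit.errors.PipelineError` carrying
the stage name and subject id; partial outputs are kept and listed in the
manifest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig, SubjectInput, config_hash
from .errors import PipelineError, QcError
from .mapping import QcSpec, compute_cvr_map
from .protocol import HypercapniaProtocol, detect_end_tidal, resample_to_tr
from .roi import summarize
from .stats import CohortTable, run_standard_analyses

__all__ = ["run_pipeline", "process_subject", "simulate_study"]

log = logging.getLogger("cvrkit")

IMAGING_COLUMNS = (
    "gm_cvr", "wm_cvr", "brain_cvr", "gm_volume_cm3", "wm_volume_cm3",
    "petco2_min", "petco2_max",
)


def _stage(stage: str, subject: str | None):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage=%s subject=%s failed after %.2fs: %s",
                          stage, subject, dt, exc)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(stage, subject, exc) from exc
                return False
            log.info("stage=%s subject=%s done in %.2fs", stage, subject, dt)
            return False

    return _Ctx()


def process_subject(
    sub: SubjectInput, config: RunConfig, base_dir: Path, out_dir: Path
) -> dict:
    """Run the imaging chain for one subject; returns its scalar row."""

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base_dir / q

    with _stage("read-bold", sub.subject_id):
        bold = cio.read_bold_nifti(resolve(sub.bold), tr_s=sub.tr_s)
        masks = cio.read_masks_nifti(resolve(sub.masks))

    with _stage("capno", sub.subject_id):
        trace = cio.read_capno_csv(resolve(sub.capno))
        ets = detect_end_tidal(trace, config.mapping.min_breath_interval_s)
        reg = resample_to_tr(ets, bold.tr_s, bold.n_volumes)

    with _stage("qc", sub.subject_id):
        censor = cio.read_censor_file(resolve(sub.censor)) if sub.censor else frozenset()
        if config.qc.n_discard >= bold.n_volumes:
            raise QcError(
                f"n_discard={config.qc.n_discard} >= n_volumes={bold.n_volumes}"
            )
        qc = QcSpec(config.qc.n_discard, censor, config.qc.max_censor)

    with _stage("map", sub.subject_id):
        cvr = compute_cvr_map(
            bold, reg, qc=qc, analysis_mask=masks.head,
            baseline_mmHg=config.protocol.baseline_mmHg,
            signal_floor=config.mapping.signal_floor,
            lag_search=config.mapping.lag_search,
            lag_window=config.mapping.lag_window,
        )
        prefix = out_dir / f"{sub.subject_id}_v{sub.visit}"
        cio.write_cvr_map(cvr, prefix, bold.voxel_size_mm)

    with _stage("summarize", sub.subject_id):
        report = summarize(cvr, masks)
        cio.write_roi_report(report, f"{prefix}_roi.csv", f"{prefix}_roi.json")

    row = {"subject_id": sub.subject_id, "group": sub.group, "visit": sub.visit}
    row.update(report.to_dict())
    row["petco2_min"] = float(reg.values_mmHg.min())
    row["petco2_max"] = float(reg.values_mmHg.max())
    return row


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> dict:
    """Execute the configured study analysis; returns an artifact manifest."""
    base_dir = Path(base_dir)
    out_dir = base_dir / config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    manifest_path = out_dir / "manifest.json"

    imaging_rows = []
    try:
        for sub in config.subjects:
            row = process_subject(sub, config, base_dir, out_dir)
            imaging_rows.append(row)
            artifacts.append(f"{sub.subject_id}_v{sub.visit}_roi.csv")

        table = None
        if config.cohort_csv is not None:
            with _stage("cohort-load", None):
                p = Path(config.cohort_csv)
                table = CohortTable.from_csv(p if p.is_absolute() else base_dir / p)
        if imaging_rows:
            with _stage("cohort-merge", None):
                table = _merge_imaging(table, imaging_rows)
        if table is None:
            raise PipelineError("cohort", None,
                                ValueError("no subjects and no cohort_csv configured"))

        cohort_out = out_dir / "cohort.csv"
        table.to_csv(cohort_out)
        artifacts.append("cohort.csv")

        with _stage("stats", None):
            results = run_standard_analyses(table, alpha=config.stats.alpha)
            results.to_csv(out_dir / "stats_report.csv", index=False)
            (out_dir / "stats_report.txt").write_text(_render_report(results))
            artifacts += ["stats_report.csv", "stats_report.txt"]
    finally:
        manifest = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "artifacts": sorted(artifacts),
            "n_imaging_subjects": len(imaging_rows),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest


def _merge_imaging(table: CohortTable | None, rows: list[dict]) -> CohortTable:
    """Overlay imaging-derived scalars onto the metadata table."""
    derived = pd.DataFrame(rows)
    if table is None:
        df = derived.copy()
        for col in ("age_years", "sex", "days_post_injury", "scat2", "sss"):
            if col not in df.columns:
                df[col] = np.nan
        return CohortTable(df)
    df = table.df.copy()
    for _, r in derived.iterrows():
        sel = (df["subject_id"] == r["subject_id"]) & (df["visit"] == r["visit"])
        if not sel.any():
            add = {c: r.get(c, np.nan) for c in df.columns}
            df = pd.concat([df, pd.DataFrame([add])], ignore_index=True)
            sel = (df["subject_id"] == r["subject_id"]) & (df["visit"] == r["visit"])
        for col in IMAGING_COLUMNS:
            if col in r and pd.notna(r[col]):
                df.loc[sel, col] = r[col]
    return CohortTable(df)


def _render_report(results: pd.DataFrame) -> str:
    lines = ["cvrkit statistical report", "=" * 40]
    for section, chunk in results.groupby("section", sort=False):
        lines.append("")
        lines.append(f"[{section}]")
        for _, r in chunk.iterrows():
            p = "" if pd.isna(r["p_value"]) else f"  p={r['p_value']:.4g}"
            est = "" if r["estimate"] is None or pd.isna(r["estimate"]) else \
                f"  est={r['estimate']:.4g}"
            lines.append(
                f"  {r['variable']:<28s} {r['group']:<16s} {r['method']:<24s}"
                f" stat={r['statistic']:.4g}{p}{est}  n={r['n']}"
            )
    return "\n".join(lines) + "\n"


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    n_imaging_subjects: int = 2,
    grid_dims: tuple[int, int, int] = (12, 12, 6),
    n_volumes: int = 255,
    noise_sd: float = 2.0,
) -> Path:
    """Write a self-contained synthetic study directory with a config.yaml.

    A cohort table provides subject scalars; for ``n_imaging_subjects``
    mTBI visit-1 subjects, a phantom BOLD series (compartment reactivities
    set to that subject's cohort GM/WM CVR), tissue masks and a simulated
    capnograph trace are written so the full imaging chain can run.
    """
    import yaml

    from .protocol import build_protocol_waveform, simulate_capnograph
    from .synth import (Compartment, PhantomSpec, generate_phantom,
                        mtbi_tissue_compartments, study_cohort_params,
                        generate_cohort)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    cohort = generate_cohort(study_cohort_params(seed=rng_seed))
    cohort.to_csv(out / "cohort.csv")

    protocol = HypercapniaProtocol()
    tr = 2.0
    reg = build_protocol_waveform(protocol, tr, n_volumes)

    subjects = []
    mtbi_v1 = cohort.subset(group="mtbi", visit=1).head(n_imaging_subjects)
    for i, (_, row) in enumerate(mtbi_v1.iterrows()):
        sid = row["subject_id"]
        comps = mtbi_tissue_compartments(noise_sd=noise_sd)
        comps["gm"] = Compartment(row["gm_cvr"], 1000.0, noise_sd)
        comps["wm"] = Compartment(row["wm_cvr"], 800.0, noise_sd)
        spec = PhantomSpec(
            grid_dims=grid_dims, tr_s=tr, n_volumes=n_volumes,
            baseline_mmHg=protocol.baseline_mmHg, compartments=comps,
            seed=rng_seed + 17 * (i + 1),
        )
        bold, masks, _ = generate_phantom(spec, reg)
        cio.write_bold_nifti(bold, out / f"{sid}_bold.nii.gz")
        cio.write_masks_nifti(masks, out / f"{sid}_masks.nii.gz")
        trace = simulate_capnograph(
            protocol, noise_sd_mmHg=0.5, seed=rng_seed + 31 * (i + 1)
        )
        cio.write_capno_csv(trace, out / f"{sid}_capno.csv")
        subjects.append({
            "subject_id": sid, "group": "mtbi", "visit": 1,
            "bold": f"{sid}_bold.nii.gz", "capno": f"{sid}_capno.csv",
            "masks": f"{sid}_masks.nii.gz", "tr_s": tr,
        })

    cfg = {
        "protocol": {"baseline_mmHg": protocol.baseline_mmHg},
        "subjects": subjects,
        "cohort_csv": "cohort.csv",
        "out_dir": "results",
        "seed": rng_seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out / "config.yaml"
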