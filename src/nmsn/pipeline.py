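"""Reproducible orchestration: simulate -> quantify -> reliability -> stats -> power.

A single JSON-serializable :class:`RunConfig` drives the whole run. Every
output CSV starts with a comment line carrying the config hash and seed,
NIfTI headers carry the same stamp in ``descrip``, and the run report
aggregates per-stage output hashes and exclusion accounting, so two runs
with the same config are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import quantify as q
from . import reliability as rel
from . import stats as st
from . import power as pw
from .synthetic import (
    CohortDesign,
    PhantomSpec,
    RaterPerturbation,
    generate_cohort,
    generate_phantom,
    perturb_mask,
)

logger = logging.getLogger(__name__)

SUBJECT_TABLE_COLUMNS = [
    "subject_id", "visit", "group", "sex", "age", "scanner", "delay_years",
    "tiv_cm3", "updrs3_off", "disease_duration_yr", "hy_stage", "ledd_mg",
]

SN_LABEL, BND_LABEL = 1, 2


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateParams(_Forbid):
    cohort: Literal["early", "progressing"] = "early"
    design_overrides: dict[str, Any] = Field(default_factory=dict)
    phantom_overrides: dict[str, Any] = Field(default_factory=dict)
    write_images: bool = True


class QuantifyParams(_Forbid):
    min_voxels: int = 1
    ddof: int = 1


class ReliabilityParams(_Forbid):
    boundary_shift_prob: float = 0.5


class StatsParams(_Forbid):
    design: Literal["cohort1", "cohort2"] = "cohort1"
    n_perm: int = 2000
    clinical_vars: list[str] = Field(
        default_factory=lambda: ["updrs3_off", "disease_duration_yr", "age"]
    )


class PowerParams(_Forbid):
    effect_fractions: list[float] = Field(default_factory=lambda: [0.3, 0.5, 0.7])
    powers: list[float] = Field(default_factory=lambda: [0.9, 0.8])
    alpha: float = 0.05
    method: Literal["analytic", "simulation"] = "analytic"
    delta_reference: Literal["difference", "pd"] = "difference"


class RunConfig(_Forbid):
    """Schema-validated configuration of one pipeline run."""

    stages: list[Literal["simulate", "quantify", "reliability", "stats", "power"]]
    out_dir: str
    seed: int = 0
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    quantify: QuantifyParams = Field(default_factory=QuantifyParams)
    reliability: ReliabilityParams = Field(default_factory=ReliabilityParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    power: PowerParams = Field(default_factory=PowerParams)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded), so runs
        that differ only in output location stay byte-identical."""
        payload = self.model_dump(exclude={"out_dir"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stamp(config: RunConfig) -> str:
    return f"nmsn config={config.config_hash()} seed={config.seed}"


def write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _nifti(data: np.ndarray, voxel_size, stamp: str) -> nib.Nifti1Image:
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header["descrip"] = stamp.encode()[:79]
    return img


def write_phantom_nifti(
    image: q.NMImageVolume, masks: q.ROIMaskPair, img_path: Path, labels_path: Path,
    stamp: str = "nmsn",
) -> None:
    """Write the image and a single labelmap (1 = SN, 2 = background)."""
    nib.save(_nifti(image.data.astype(np.float32), image.voxel_size, stamp), img_path)
    labels = np.zeros(masks.shape, dtype=np.uint8)
    labels[masks.sn_mask] = SN_LABEL
    labels[masks.bnd_mask] = BND_LABEL
    nib.save(_nifti(labels, image.voxel_size, stamp), labels_path)


def read_phantom_nifti(img_path: Path, labels_path: Path) -> tuple[q.NMImageVolume, q.ROIMaskPair]:
    """Read an image plus labelmap written by :func:`write_phantom_nifti`."""
    img = nib.load(str(img_path))
    lab = nib.load(str(labels_path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(lab.dataobj)
    return (
        q.NMImageVolume(data=np.asarray(img.dataobj, dtype=float), voxel_size=voxel_size),
        q.ROIMaskPair(sn_mask=labels == SN_LABEL, bnd_mask=labels == BND_LABEL),
    )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject-visit CSV (units: TIV cm^3, LEDD mg, delay yr)."""
    df = read_csv(Path(path))
    missing = [c for c in SUBJECT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing mandatory columns {missing}")
    problems = []
    bad_visit = ~df["visit"].isin(["V1", "V2"])
    if bad_visit.any():
        problems.append(f"invalid visit labels at rows {list(df.index[bad_visit])}")
    dup = df.duplicated(subset=["subject_id", "visit"], keep=False)
    if dup.any():
        problems.append(f"duplicated (subject, visit) pairs at rows {list(df.index[dup])}")
    bad_age = df["age"] <= 0
    if bad_age.any():
        problems.append(f"nonpositive age at rows {list(df.index[bad_age])}")
    bad_hy = df["hy_stage"].notna() & ~df["hy_stage"].between(0, 5)
    if bad_hy.any():
        problems.append(f"Hoehn-Yahr outside [0, 5] at rows {list(df.index[bad_hy])}")
    bad_tiv = df["tiv_cm3"] <= 0
    if bad_tiv.any():
        problems.append(f"nonpositive TIV at rows {list(df.index[bad_tiv])}")
    if problems:
        raise ValueError("subject table validation failed: " + "; ".join(problems))
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, out: Path, report: dict) -> None:
    p = config.simulate
    design_cls = CohortDesign.early_pd if p.cohort == "early" else CohortDesign.progressing_pd
    design = design_cls(seed=config.seed, **p.design_overrides)
    phantom = PhantomSpec(**p.phantom_overrides)
    subjects, phantoms = generate_cohort(design, phantom=phantom)
    stamp = _stamp(config)
    write_csv(subjects, out / "cohort.csv", stamp)
    write_csv(phantoms, out / "phantoms.csv", stamp)
    if p.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for row in phantoms.itertuples():
            spec = _row_phantom_spec(phantom, row)
            image, masks = generate_phantom(spec, seed=int(row.render_seed))
            base = f"{row.subject_id}_{row.visit}"
            write_phantom_nifti(
                image, masks, img_dir / f"{base}_img.nii.gz",
                img_dir / f"{base}_labels.nii.gz", stamp,
            )
    report["simulate"] = {"n_rows": len(subjects), "images_written": bool(p.write_images)}


def _row_phantom_spec(template: PhantomSpec, row) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=template.grid_shape,
        voxel_size=template.voxel_size,
        bnd_mean=float(row.bnd_mean),
        bnd_sd=float(row.bnd_sd),
        sn_target_volume=float(row.sn_target_volume),
        sn_target_snr=float(row.sn_target_snr),
        n_sn_slices=int(row.n_sn_slices),
    )


def _stage_quantify(config: RunConfig, out: Path, report: dict) -> None:
    subjects = read_subject_table(out / "cohort.csv")
    phantoms = read_csv(out / "phantoms.csv")
    template = PhantomSpec(**config.simulate.phantom_overrides)
    img_dir = out / "images"
    qp = config.quantify
    rows, excluded = [], []
    tiv = subjects.set_index(["subject_id", "visit"])["tiv_cm3"]
    for row in phantoms.itertuples():
        base = f"{row.subject_id}_{row.visit}"
        try:
            if (img_dir / f"{base}_img.nii.gz").exists():
                image, masks = read_phantom_nifti(
                    img_dir / f"{base}_img.nii.gz", img_dir / f"{base}_labels.nii.gz"
                )
            else:
                image, masks = generate_phantom(
                    _row_phantom_spec(template, row), seed=int(row.render_seed)
                )
            m = q.measure(
                image, masks, tiv_cm3=float(tiv.loc[(row.subject_id, row.visit)]),
                min_voxels=qp.min_voxels, ddof=qp.ddof,
            )
        except (q.SNNotMeasurableError, ValueError) as err:
            excluded.append({"subject_id": row.subject_id, "visit": row.visit, "reason": str(err)})
            continue
        rows.append(
            dict(subject_id=row.subject_id, visit=row.visit, vol_mm3=m.vol_mm3,
                 cvol=m.cvol, snr=m.snr, cnr=m.cnr,
                 slices_used="|".join(map(str, m.slices_used)))
        )
    measured = pd.DataFrame(rows)
    merged = subjects.drop(columns=["vol_mm3", "cvol", "snr", "cnr"], errors="ignore").merge(
        measured, on=["subject_id", "visit"], how="inner"
    )
    # measured values are canonical downstream; rename to the measure names
    merged = merged.rename(columns={"vol_mm3": "vol"})
    write_csv(merged, out / "measurements.csv", _stamp(config))
    report["quantify"] = {"n_measured": len(merged), "n_excluded": len(excluded),
                          "exclusions": excluded}


def _stage_reliability(config: RunConfig, out: Path, report: dict) -> None:
    phantoms = read_csv(out / "phantoms.csv")
    subjects = read_subject_table(out / "cohort.csv")
    template = PhantomSpec(**config.simulate.phantom_overrides)
    tiv = subjects.set_index(["subject_id", "visit"])["tiv_cm3"]
    shift = config.reliability.boundary_shift_prob
    dices, vols_a, vols_b, snrs_a, snrs_b = [], [], [], [], []
    baseline = phantoms[phantoms["visit"] == "V1"]
    for i, row in enumerate(baseline.itertuples()):
        image, masks = generate_phantom(
            _row_phantom_spec(template, row), seed=int(row.render_seed)
        )
        rater2 = perturb_mask(
            masks.sn_mask,
            RaterPerturbation(boundary_shift_prob=shift, seed=int(row.render_seed) + 1),
        )
        dices.append(rel.dice(masks.sn_mask, rater2))
        t = float(tiv.loc[(row.subject_id, row.visit)])
        m_a = q.measure(image, masks, t)
        m_b = q.measure(image, q.ROIMaskPair(rater2, masks.bnd_mask & ~rater2), t)
        vols_a.append(m_a.vol_mm3)
        vols_b.append(m_b.vol_mm3)
        snrs_a.append(m_a.snr)
        snrs_b.append(m_b.snr)
    result = {
        "dice_mean": float(np.mean(dices)),
        "icc_vol": rel.icc(rel.RatingsMatrix(np.column_stack([vols_a, vols_b]), "vol")),
        "icc_snr": rel.icc(rel.RatingsMatrix(np.column_stack([snrs_a, snrs_b]), "snr")),
        "n_scans": len(dices),
        "boundary_shift_prob": shift,
        "stamp": _stamp(config),
    }
    (out / "reliability.json").write_text(json.dumps(result, indent=2))
    report["reliability"] = {k: result[k] for k in ("dice_mean", "icc_vol", "icc_snr", "n_scans")}


def _stage_stats(config: RunConfig, out: Path, report: dict) -> None:
    sp = config.stats
    table = read_csv(out / "measurements.csv")
    baseline = table[table["visit"] == "V1"]
    results = []
    for m in q.MEASURES:
        cs = st.cross_sectional_model(baseline, m)
        cs.insert(0, "analysis", f"cross_sectional:{m}")
        results.append(cs)
        lg, n_excl = st.longitudinal_model(table, m, design=sp.design)
        lg.insert(0, "analysis", f"longitudinal:{m}")
        results.append(lg)
        report.setdefault("stats", {}).setdefault("longitudinal_excluded", {})[m] = n_excl
    hv_base = baseline[baseline["group"] == "HV"]
    if hv_base["scanner"].nunique() >= 2:
        for m in q.MEASURES:
            sc = st.scanner_effect(hv_base, m)
            sc.insert(0, "analysis", f"scanner:{m}")
            results.append(sc)
    stamp = _stamp(config)
    write_csv(pd.concat(results, ignore_index=True), out / "stats_results.csv", stamp)

    aucs = {
        m: st.roc_auc(baseline[m], baseline["group"], positive_group="PD")._asdict()
        for m in q.MEASURES
    }
    (out / "roc.json").write_text(json.dumps({"stamp": stamp, "auc": aucs}, indent=2))

    pd_base = baseline[baseline["group"] == "PD"]
    corr = st.correlation_with_permutation(
        pd_base, measures=list(q.MEASURES), clinical_vars=sp.clinical_vars,
        n_perm=sp.n_perm, seed=config.seed,
    )
    write_csv(corr, out / "correlations.csv", stamp)
    report["stats"]["n_tests"] = int(sum(len(r) for r in results))


def _stage_power(config: RunConfig, out: Path, report: dict) -> None:
    pp = config.power
    table = read_csv(out / "measurements.csv")
    changes_pd = pw.annualized_changes(table, group="PD")
    try:
        changes_hv = pw.annualized_changes(table, group="HV")
    except ValueError:
        changes_hv = None
    queries = pw.queries_from_changes(
        changes_pd, changes_hv, effect_fractions=pp.effect_fractions,
        powers=pp.powers, alpha=pp.alpha, delta_reference=pp.delta_reference,
    )
    grid = pw.power_table(queries, method=pp.method, seed=config.seed)
    write_csv(grid.reset_index(), out / "power.csv", _stamp(config))
    report["power"] = {"n_cells": int(grid.size)}


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "reliability": _stage_reliability,
    "stats": _stage_stats,
    "power": _stage_power,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write ``report.json``.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are hashed into the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_run": [],
    }
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            _STAGES[stage](config, out, report)
        except Exception as err:
            report["failed_stage"] = stage
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        report["stages_run"].append(stage)
    report["output_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
        if p.name != "report.json"
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
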