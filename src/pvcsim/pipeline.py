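"""End-to-end experiment orchestration.

The experiment shape is: simulate a cohort -> build four SUV variants per
subject (uncorrected, Meltzer, mMG, RBV) -> sample GM-only VOI and
cerebellar-GM SUVRs -> percent-change and correlation report.  Each stage
reads and writes only standard formats (NIfTI volumes, CSV tables, JSON
sidecars), so real co-registered inputs can replace the simulation stage
without code changes, and any stage can be rerun in isolation from the files
of the previous one.

``run_experiment`` drives the whole chain in memory (optionally writing all
per-subject volumes) and is deterministic: identical config + seed
reproduces every CSV byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    DEFAULT_ALPHA,
    correlation_report,
    percent_change_table,
    summarize_report,
)
from .images import (
    Image3D,
    SubjectMeta,
    read_image,
    read_parcellation,
    to_suv,
    validate_parcellation,
    write_image,
    write_parcellation,
)
from .phantom import CohortDataset, CohortSpec, PhantomSpec, SubjectData, simulate_cohort
from .psf import PSFModel, make_kernel, convolve_array
from .pvc import (
    PVCResult,
    meltzer_correct,
    mmg_correct,
    no_correction,
    rbv_correct,
)
from .sampling import MIN_VOI_VOXELS, compute_suvr, restrict_voi_to_gm

logger = logging.getLogger(__name__)

METHODS = ("none", "meltzer", "mmg", "rbv")


@dataclass(frozen=True)
class CorrectionParams:
    """Knobs of the three corrections (shared PSF unless overridden)."""

    fwhm_mm: tuple[float, float, float] | None = None  # None: cohort scanner PSF
    tau: float = 0.1
    tau_gm: float = 0.1
    wm_mode: str = "gtm2"
    eps: float | None = None
    clamp_negative: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one experiment run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    min_voi_voxels: int = MIN_VOI_VOXELS
    alpha: float = DEFAULT_ALPHA

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, sub: dict):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return klass(**sub)

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = build(CohortSpec, raw["cohort"])
        if "phantom" in raw:
            kwargs["phantom"] = build(PhantomSpec, raw["phantom"])
        if "correction" in raw:
            kwargs["correction"] = build(CorrectionParams, raw["correction"])
        for key in ("min_voi_voxels", "alpha"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def correction_psf(self) -> PSFModel:
        fwhm = (
            self.correction.fwhm_mm
            if self.correction.fwhm_mm is not None
            else self.cohort.fwhm_mm
        )
        return PSFModel(fwhm_mm=tuple(fwhm))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-subject correction
# ---------------------------------------------------------------------------


def correct_subject(
    suv: Image3D,
    masks: dict[str, Image3D],
    parc,
    psf: PSFModel,
    params: CorrectionParams = CorrectionParams(),
) -> dict[str, PVCResult]:
    """All four SUV variants for one subject.

    Smoothed region masks are computed once and shared between the GTM/RBV
    stage and the whole-brain/GM/WM smooths (which are sums of region
    smooths for a parcellation that tiles the brain), since convolution is
    linear.
    """
    kernel = make_kernel(psf, suv.voxel_size_mm)
    smoothed = {
        lab: convolve_array((parc.labelmap == lab).astype(np.float64), kernel)
        for lab in parc.labels
    }
    results = {"none": no_correction(suv, masks["brain"])}
    results["meltzer"] = meltzer_correct(suv, masks["brain"], psf, tau=params.tau)
    results["mmg"] = mmg_correct(
        suv,
        masks["gm"],
        masks["wm"],
        psf,
        tau_gm=params.tau_gm,
        wm_mode=params.wm_mode,
        clamp_negative=params.clamp_negative,
    )
    results["rbv"] = rbv_correct(
        suv, parc, psf, eps=params.eps, smoothed_masks=smoothed
    )
    return results


def subject_suv(subject: SubjectData) -> Image3D:
    """Observed activity image scaled to SUV for one simulated subject."""
    return to_suv(subject.observed, subject.meta)


def cohort_suvr_table(
    cohort: CohortDataset,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """SUVR records (4 methods x n subjects) for a simulated cohort."""
    if config is None:
        config = RunConfig(cohort=cohort.cohort_spec, phantom=cohort.phantom_spec)
    psf = config.correction_psf
    records = []
    for subject in cohort.subjects:
        suv = subject_suv(subject)
        results = correct_subject(
            suv, subject.masks, subject.parcellation, psf, config.correction
        )
        records.extend(
            suvr_records_for_subject(subject, results, config.min_voi_voxels)
        )
    return pd.DataFrame(records)


def suvr_records_for_subject(
    subject: SubjectData,
    results: dict[str, PVCResult],
    min_voi_voxels: int = MIN_VOI_VOXELS,
) -> list[dict]:
    from .images import binarize_labels

    # cerebellar GM mask from the parcellation region names
    cereb_labels = [
        lab
        for lab, name in subject.parcellation.region_table.items()
        if name.startswith("cerebellar_gm")
    ]
    cereb_gm = binarize_labels(subject.parcellation, cereb_labels)
    voi_gm = restrict_voi_to_gm(subject.voi, subject.masks["gm"], min_voi_voxels)
    out = []
    for method in METHODS:
        rec = compute_suvr(
            results[method], voi_gm, cereb_gm, subject_id=subject.meta.subject_id
        )
        out.append(vars(rec))
    return out


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: str | Path) -> CohortDataset:
    """Simulate a cohort and write every subject volume plus the tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.cohort, config.phantom)
    for subject in cohort.subjects:
        sid = subject.meta.subject_id
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        write_image(subject.truth, sdir / "truth.nii")
        write_image(subject.observed, sdir / "activity.nii")
        for name, mask in subject.masks.items():
            write_image(mask, sdir / f"mask_{name}.nii")
        write_image(subject.voi, sdir / "voi.nii")
        write_parcellation(subject.parcellation, sdir / "parcellation.nii")
        (sdir / "regions.json").write_text(
            json.dumps(
                {str(k): v for k, v in subject.parcellation.region_table.items()},
                indent=2,
            )
        )
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    cohort.histology.to_csv(outdir / "histology.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(
            {"pvcsim_version": __version__, **_jsonable(cohort.generative_record)},
            indent=2,
        )
    )
    return cohort


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_subject(sdir: str | Path, meta: SubjectMeta):
    """Reload one subject's volumes written by :func:`stage_simulate`."""
    sdir = Path(sdir)
    region_table = {
        int(k): v for k, v in json.loads((sdir / "regions.json").read_text()).items()
    }
    return SubjectData(
        meta=meta,
        load=np.nan,
        truth=read_image(sdir / "truth.nii"),
        observed=read_image(sdir / "activity.nii"),
        masks={
            name: read_image(sdir / f"mask_{name}.nii")
            for name in ("brain", "gm", "wm")
        },
        parcellation=read_parcellation(sdir / "parcellation.nii", region_table),
        voi=read_image(sdir / "voi.nii"),
    )


def stage_correct(
    cohort_dir: str | Path, outdir: str | Path, config: RunConfig
) -> None:
    """Apply the four correction variants to every stored subject."""
    cohort_dir, outdir = Path(cohort_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    psf = config.correction_psf
    for _, row in meta.iterrows():
        subject = load_subject(
            cohort_dir / row["subject_id"],
            SubjectMeta(row["subject_id"], row["weight_kg"], row["dose_kbq"]),
        )
        suv = subject_suv(subject)
        results = correct_subject(
            suv, subject.masks, subject.parcellation, psf, config.correction
        )
        sdir = outdir / row["subject_id"]
        sdir.mkdir(exist_ok=True)
        for method, result in results.items():
            result.write(sdir / method)


def stage_suvr(
    cohort_dir: str | Path,
    corrected_dir: str | Path,
    out_csv: str | Path,
    config: RunConfig,
) -> pd.DataFrame:
    """Sample SUVRs from stored corrected images into one CSV."""
    cohort_dir, corrected_dir = Path(cohort_dir), Path(corrected_dir)
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        sid = row["subject_id"]
        subject = load_subject(
            cohort_dir / sid, SubjectMeta(sid, row["weight_kg"], row["dose_kbq"])
        )
        results = {}
        for method in METHODS:
            corrected = read_image(corrected_dir / sid / f"{method}.nii")
            validity = read_image(corrected_dir / sid / f"{method}_validity.nii")
            results[method] = PVCResult(
                corrected=corrected,
                validity=validity.data,
                method=method,
                params=json.loads(
                    (corrected_dir / sid / f"{method}.json").read_text()
                ),
            )
        records.extend(
            suvr_records_for_subject(subject, results, config.min_voi_voxels)
        )
    table = pd.DataFrame(records)
    table.to_csv(out_csv, index=False)
    return table


def stage_report(
    suvr_csv: str | Path,
    histology_csv: str | Path,
    outdir: str | Path,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-change and correlation report from stored CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suvr = pd.read_csv(suvr_csv, float_precision="round_trip")
    histology = pd.read_csv(histology_csv, float_precision="round_trip")
    pct = percent_change_table(suvr)
    corr = correlation_report(suvr, histology, alpha=alpha)
    pct.to_csv(outdir / "percent_change.csv", index=False)
    corr.to_csv(outdir / "correlations.csv", index=False)
    (outdir / "summary.txt").write_text(summarize_report(pct, corr, alpha) + "\n")
    return pct, corr


@dataclass
class ExperimentResult:
    cohort: CohortDataset
    suvr: pd.DataFrame
    percent_change: pd.DataFrame
    correlations: pd.DataFrame
    summary: str


def run_experiment(
    config: RunConfig,
    outdir: str | Path,
    write_images: bool = False,
) -> ExperimentResult:
    """Full chain: simulate -> correct -> SUVR -> report.

    With ``write_images`` every per-subject volume and corrected image is
    written under ``outdir`` (the file-based stage layout); otherwise only
    the CSV tables, summary and manifest are written.  All CSV output is
    byte-identical across reruns with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if write_images:
        cohort = stage_simulate(config, outdir / "cohort")
    else:
        cohort = simulate_cohort(config.cohort, config.phantom)
    for subject in cohort.subjects:
        validate_parcellation(subject.parcellation, subject.masks["brain"])
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    psf = config.correction_psf
    records = []
    for subject in cohort.subjects:
        suv = subject_suv(subject)
        results = correct_subject(
            suv, subject.masks, subject.parcellation, psf, config.correction
        )
        if write_images:
            sdir = outdir / "corrected" / subject.meta.subject_id
            sdir.mkdir(parents=True, exist_ok=True)
            for method, result in results.items():
                result.write(sdir / method)
        records.extend(
            suvr_records_for_subject(subject, results, config.min_voi_voxels)
        )
    suvr = pd.DataFrame(records)
    timings["correct_and_suvr"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    suvr.to_csv(outdir / "suvr.csv", index=False)
    cohort.histology.to_csv(outdir / "histology.csv", index=False)
    pct = percent_change_table(suvr)
    corr = correlation_report(suvr, cohort.histology, alpha=config.alpha)
    pct.to_csv(outdir / "percent_change.csv", index=False)
    corr.to_csv(outdir / "correlations.csv", index=False)
    summary = summarize_report(pct, corr, config.alpha)
    (outdir / "summary.txt").write_text(summary + "\n")
    timings["report"] = time.perf_counter() - t0

    manifest = {
        "pvcsim_version": __version__,
        "config": _jsonable(asdict(config)),
        "config_digest": config.digest(),
        "seed": config.cohort.seed,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("experiment complete: %s", outdir)
    return ExperimentResult(
        cohort=cohort,
        suvr=suvr,
        percent_change=pct,
        correlations=corr,
        summary=summary,
    )
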