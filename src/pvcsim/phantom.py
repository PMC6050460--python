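"""Digital brain phantoms and simulated subject cohorts.

The phantom is an analytic ellipsoid-shell model of a brain on a regular
voxel grid: a cerebral WM ellipsoid wrapped in a cortical GM ribbon of
controllable thickness, plus a separate cerebellar GM shell / WM core used as
the SUVR reference region.  The GM ribbon is split into azimuthal sectors so
the parcellation has within-GM anatomical boundaries; one sector hosts the
target ("precuneus-like") VOI.  Activity is piecewise constant per region,
with nonspecific WM uptake and a target-GM activity driven by a latent
pathology load.

Two disease-relevant mechanisms are built in:

* WM cross-contamination — the GM ribbon sits directly on WM at every
  thickness, and radial gyral WM fingers reach into the ribbon at a spatial
  period below twice the scanner FWHM, so nonspecific WM signal spills into
  cortex laterally as well as from below (as it does in folded cortex);
* load-coupled atrophy — GM thickness shrinks with pathology load, the
  ribbon's outer surface retracting from the brain envelope so CSF expands
  on the pial/sulcal side: the classic confound of CSF-bordering cortical
  thinning.

The cerebellar GM shell is thicker (default 8 mm) and not coupled to load,
reflecting neocortex-dominant atrophy; the reference region is therefore
less partial-volume-affected than the target VOI.

A simulated scan is the truth convolved with the scanner PSF plus i.i.d.
Gaussian noise scaled to the whole-brain mean.  A cohort draws a pathology
load per subject and derives target-GM activity, GM thickness and two noisy
histology percent-area measures (emulating a fluorescent-compound and an
antibody stain) from it, so imaging and histology share a single latent
cause.  All randomness flows from one seeded generator in a fixed draw
order: loads first, then per-subject scan noise, then histology errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .images import Image3D, Parcellation, SubjectMeta, make_mask
from .psf import PSFModel, convolve_array, make_kernel
from .pvc import insert_voi_into_parcellation

# label layout: GM sectors are 1..K, then the fixed tissue labels follow
_WM_OFFSET = 1
_CEREB_GM_OFFSET = 2
_CEREB_WM_OFFSET = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of a single digital brain phantom.

    Lengths in mm, activities in arbitrary concentration units (they behave
    like SUV after scaling).  The GM ribbon is the shell of thickness
    ``gm_thickness_mm`` sitting on the WM ellipsoid; ``brain_semiaxes_mm``
    is the outer brain envelope (WM semi-axes plus the baseline thickness by
    default).  A thinner ribbon retracts from the envelope, leaving CSF on
    the outer side while staying attached to WM — the anatomy of cortical
    atrophy.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes_mm: tuple[float, float, float] = (60.0, 70.0, 52.0)
    brain_center_mm: tuple[float, float, float] = (0.0, 8.0, 18.0)
    wm_semiaxes_mm: tuple[float, float, float] = (56.0, 66.0, 48.0)
    gm_thickness_mm: float = 4.0
    n_gm_sectors: int = 8
    cereb_semiaxes_mm: tuple[float, float, float] = (30.0, 35.0, 25.0)
    cereb_center_mm: tuple[float, float, float] = (0.0, -45.0, -55.0)
    cereb_wm_semiaxes_mm: tuple[float, float, float] = (16.0, 19.0, 11.0)
    cereb_gm_thickness_mm: float = 6.0
    # gyral WM fingers reaching radially into the cortical ribbon; the
    # cerebellum stays smooth (its folia are far below PET resolution)
    n_gyri: int = 30
    gyral_depth_frac: float = 0.7
    gyral_width: float = 0.6  # sin(n_gyri * theta) threshold; higher = thinner
    a_csf: float = 0.0
    a_wm: float = 1.5
    a_gm_other: float = 1.4
    a_gm_target: float = 2.5
    a_ref: float = 1.0
    a_cereb_wm: float = 1.5
    target_sector: int = 1

    def __post_init__(self) -> None:
        if self.n_gm_sectors < 1:
            raise ValueError("need at least one GM sector")
        if not (1 <= self.target_sector <= self.n_gm_sectors):
            raise ValueError("target_sector out of range")
        if any(
            w >= b for w, b in zip(self.wm_semiaxes_mm, self.brain_semiaxes_mm)
        ):
            raise ValueError("WM ellipsoid must lie strictly inside the brain")
        if any(
            w >= c
            for w, c in zip(self.cereb_wm_semiaxes_mm, self.cereb_semiaxes_mm)
        ):
            raise ValueError("cerebellar WM must lie strictly inside the cerebellum")
        for a in (
            self.a_csf,
            self.a_wm,
            self.a_gm_other,
            self.a_gm_target,
            self.a_ref,
            self.a_cereb_wm,
        ):
            if a < 0:
                raise ValueError("activities must be nonnegative")
        if self.gm_thickness_mm <= 0 or self.cereb_gm_thickness_mm <= 0:
            raise ValueError("GM thickness must be positive")
        if not (0 <= self.gyral_depth_frac < 1):
            raise ValueError("gyral_depth_frac must lie in [0, 1)")
        if self.n_gyri < 0:
            raise ValueError("n_gyri must be nonnegative")

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """Same mm geometry on a coarser 64x64x64, 3 mm grid."""
        return cls(dims=(64, 64, 64), voxel_size_mm=(3.0, 3.0, 3.0), **overrides)

    # label helpers -------------------------------------------------------
    @property
    def wm_label(self) -> int:
        return self.n_gm_sectors + _WM_OFFSET

    @property
    def cereb_gm_label(self) -> int:
        return self.n_gm_sectors + _CEREB_GM_OFFSET

    @property
    def cereb_wm_label(self) -> int:
        return self.n_gm_sectors + _CEREB_WM_OFFSET


def _center_affine(spec: PhantomSpec) -> np.ndarray:
    """Axis-aligned affine placing world (0,0,0) at the grid centre."""
    affine = np.eye(4)
    for k in range(3):
        affine[k, k] = spec.voxel_size_mm[k]
        affine[k, 3] = -spec.voxel_size_mm[k] * (spec.dims[k] - 1) / 2.0
    return affine


def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    affine = _center_affine(spec)
    axes = [
        affine[k, k] * np.arange(spec.dims[k]) + affine[k, 3] for k in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _inside_ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def build_phantom(
    spec: PhantomSpec,
) -> tuple[Image3D, dict[str, Image3D], Parcellation]:
    """Construct truth image, tissue masks and parcellation for one phantom.

    Voxels are classified by world-coordinate ellipsoid tests: cerebral WM
    inside the WM ellipsoid; GM in the shell of thickness
    ``gm_thickness_mm`` on top of it (never past the brain envelope); the
    space between the GM surface and the envelope is CSF with zero
    activity.  The GM shell is split into ``n_gm_sectors`` azimuthal
    sectors.  The cerebellum is built the same way from its own ellipsoid
    pair.  Returns ``(truth, masks, parcellation)`` where ``masks`` holds
    "brain" (all tissue), "gm" (cortical + cerebellar GM) and "wm"
    (cerebral + cerebellar WM).
    """
    coords = _world_coords(spec)
    affine = _center_affine(spec)
    K = spec.n_gm_sectors
    x, y, z = coords
    theta = np.arctan2(
        y - spec.brain_center_mm[1], x - spec.brain_center_mm[0]
    )  # [-pi, pi)

    gm_outer = tuple(
        min(w + spec.gm_thickness_mm, b)
        for w, b in zip(spec.wm_semiaxes_mm, spec.brain_semiaxes_mm)
    )
    in_wm = _inside_ellipsoid(coords, spec.brain_center_mm, spec.wm_semiaxes_mm)
    in_shell = _inside_ellipsoid(coords, spec.brain_center_mm, gm_outer) & ~in_wm
    if spec.n_gyri > 0 and spec.gyral_depth_frac > 0:
        # radial WM fingers through the lower part of the ribbon
        r_wm = np.sqrt(
            sum(
                ((coords[k] - spec.brain_center_mm[k]) / spec.wm_semiaxes_mm[k]) ** 2
                for k in range(3)
            )
        )
        radius = np.sqrt(
            sum((coords[k] - spec.brain_center_mm[k]) ** 2 for k in range(3))
        )
        # approximate mm height of a shell voxel above the WM surface
        height_mm = np.where(r_wm > 0, (r_wm - 1.0) * radius / np.maximum(r_wm, 1e-9), 0.0)
        finger = (
            in_shell
            & (np.sin(spec.n_gyri * theta) > spec.gyral_width)
            & (height_mm <= spec.gyral_depth_frac * spec.gm_thickness_mm)
        )
        in_wm = in_wm | finger
        in_shell = in_shell & ~finger
    in_gm_shell = in_shell
    if not in_gm_shell.any():
        raise ValueError("degenerate geometry: empty GM shell")
    in_brain = _inside_ellipsoid(coords, spec.brain_center_mm, spec.brain_semiaxes_mm)

    in_cereb_wm = _inside_ellipsoid(
        coords, spec.cereb_center_mm, spec.cereb_wm_semiaxes_mm
    )
    cereb_gm_outer = tuple(
        min(w + spec.cereb_gm_thickness_mm, b)
        for w, b in zip(spec.cereb_wm_semiaxes_mm, spec.cereb_semiaxes_mm)
    )
    in_cereb_gm = (
        _inside_ellipsoid(coords, spec.cereb_center_mm, cereb_gm_outer)
        & ~in_cereb_wm
    )
    if (in_cereb_gm & in_brain).any() or (in_cereb_wm & in_brain).any():
        raise ValueError("cerebellum overlaps the cerebral envelope")
    if not in_cereb_gm.any() or not in_cereb_wm.any():
        raise ValueError("degenerate cerebellar geometry")

    # azimuthal sectors of the cortical shell
    sector = np.floor((theta + np.pi) / (2 * np.pi / K)).astype(np.int16)
    sector = np.clip(sector, 0, K - 1)

    labelmap = np.zeros(spec.dims, dtype=np.int16)
    labelmap[in_gm_shell] = sector[in_gm_shell] + 1
    labelmap[in_wm] = spec.wm_label
    labelmap[in_cereb_gm] = spec.cereb_gm_label
    labelmap[in_cereb_wm] = spec.cereb_wm_label

    table = {k + 1: f"gm_sector_{k + 1}" for k in range(K)}
    table[spec.wm_label] = "cerebral_wm"
    table[spec.cereb_gm_label] = "cerebellar_gm"
    table[spec.cereb_wm_label] = "cerebellar_wm"
    present = set(int(v) for v in np.unique(labelmap)) - {0}
    missing = set(table) - present
    if missing:
        raise ValueError(f"degenerate geometry: empty region(s) {sorted(missing)}")
    parc = Parcellation(labelmap=labelmap, affine=affine, region_table=table)

    truth = np.zeros(spec.dims, dtype=np.float64)
    truth[in_wm] = spec.a_wm
    truth[in_gm_shell] = spec.a_gm_other
    truth[in_gm_shell & (labelmap == spec.target_sector)] = spec.a_gm_target
    truth[in_cereb_gm] = spec.a_ref
    truth[in_cereb_wm] = spec.a_cereb_wm
    # CSF (gap voxels inside the brain ellipsoid but in no region) stays a_csf
    if spec.a_csf != 0:
        truth[in_brain & (labelmap == 0)] = spec.a_csf

    gm_mask = (labelmap >= 1) & (labelmap <= K) | in_cereb_gm
    wm_mask = in_wm | in_cereb_wm
    brain_mask = labelmap > 0
    masks = {
        "brain": make_mask(brain_mask.astype(np.uint8), affine),
        "gm": make_mask(gm_mask.astype(np.uint8), affine),
        "wm": make_mask(wm_mask.astype(np.uint8), affine),
    }
    return Image3D(data=truth, affine=affine), masks, parc


def target_voi_mask(
    spec: PhantomSpec,
    parc: Parcellation,
    radial_min: float = 0.55,
    z_halfheight_mm: float = 25.0,
) -> Image3D:
    """Autopsy-style VOI over the target sector.

    A wedge of brain tissue restricted to the target sector's azimuth, to
    the outer part of the brain (normalised ellipsoid radius above
    ``radial_min``, so the VOI spans cortex plus underlying WM like a tissue
    block) and to a slab of axial extent ``2 * z_halfheight_mm``.
    """
    coords = _world_coords(spec)
    x, y, z = coords
    K = spec.n_gm_sectors
    theta = np.arctan2(y - spec.brain_center_mm[1], x - spec.brain_center_mm[0])
    sector = np.clip(
        np.floor((theta + np.pi) / (2 * np.pi / K)).astype(np.int16), 0, K - 1
    )
    r2 = (
        ((x - spec.brain_center_mm[0]) / spec.brain_semiaxes_mm[0]) ** 2
        + ((y - spec.brain_center_mm[1]) / spec.brain_semiaxes_mm[1]) ** 2
        + ((z - spec.brain_center_mm[2]) / spec.brain_semiaxes_mm[2]) ** 2
    )
    in_wedge = (
        (sector == spec.target_sector - 1)
        & (r2 >= radial_min**2)
        & (np.abs(z - spec.brain_center_mm[2]) <= z_halfheight_mm)
        & (parc.labelmap > 0)
        & (parc.labelmap <= spec.wm_label)  # cerebrum only
    )
    if not in_wedge.any():
        raise ValueError("target VOI is empty")
    return make_mask(in_wedge.astype(np.uint8), _center_affine(spec))


def simulate_scan(
    truth: Image3D,
    psf: PSFModel,
    eta: float,
    rng: int | np.random.Generator,
    brain: Image3D | None = None,
) -> Image3D:
    """Forward model: truth convolved with the PSF plus Gaussian noise.

    Noise is i.i.d. per voxel with standard deviation ``eta`` times the mean
    truth over the brain support (whole grid when no brain mask is given);
    ``eta = 0`` is deterministic and draws nothing from the generator.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    kernel = make_kernel(psf, truth.voxel_size_mm)
    observed = convolve_array(truth.data, kernel)
    if eta > 0:
        generator = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        support = (
            truth.data != 0 if brain is None else brain.data.astype(bool)
        )
        level = float(truth.data[support].mean()) if support.any() else 0.0
        observed = observed + generator.normal(0.0, eta * level, size=observed.shape)
    return truth.with_data(observed)


@dataclass(frozen=True)
class CohortSpec:
    """Generative law of a simulated subject cohort.

    A latent pathology load L_i ~ Uniform(load_range) drives, per subject:

    * target-GM activity  a(L) = beta0 + beta1 * L,
    * cortical GM thickness d(L) = d0 - atrophy_mm_per_load * L, floored at
      d_min_mm (load-coupled atrophy),
    * two noisy histology percent-area measures
      H6 = gamma6 * L + eps6 and H4 = gamma4 * L + eps4 with
      eps ~ Normal(0, histology_sd^2), floored at 0.01 %.

    Scan noise is Gaussian with sd = eta * whole-brain mean.  Defaults echo
    a nine-subject autopsy cohort whose two histology measures span roughly
    0.25-10.5 % and 0.9-14 % area.
    """

    n_subjects: int = 9
    load_range: tuple[float, float] = (0.25, 14.0)
    beta0: float = 1.0
    beta1: float = 0.12
    atrophy_mm_per_load: float = 0.15
    d_min_mm: float = 2.0
    gamma6: float = 0.75
    gamma4: float = 1.0
    histology_sd: float = 0.8
    fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    eta: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (
            self.beta1,
            self.atrophy_mm_per_load,
            self.gamma6,
            self.gamma4,
            self.histology_sd,
            self.eta,
        ):
            if v < 0:
                raise ValueError("scale parameters must be nonnegative")
        if self.n_subjects < 3:
            raise ValueError("need at least three subjects for correlation stages")
        if self.load_range[1] < self.load_range[0]:
            raise ValueError("invalid load range")

    @classmethod
    def nc_like(cls, **overrides) -> "CohortSpec":
        """Normal-control regime: GM target stays at baseline below WM uptake.

        Pair with :func:`nc_like_phantom` so that *all* cortex, not only the
        target sector, is amyloid-free.
        """
        defaults = dict(load_range=(0.25, 2.0), beta1=0.0)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def noiseless(cls, **overrides) -> "CohortSpec":
        """Pure affine chain: no scan noise, no histology noise, no atrophy."""
        defaults = dict(eta=0.0, histology_sd=0.0, atrophy_mm_per_load=0.0)
        defaults.update(overrides)
        return cls(**defaults)


def nc_like_phantom(**overrides) -> PhantomSpec:
    """Phantom for the normal-control regime: amyloid-free cortex throughout.

    A control subject has no fibrillar amyloid anywhere in cortex, so the
    non-target GM activity drops to the reference level and only nonspecific
    WM uptake (1.5) exceeds it.
    """
    defaults = dict(a_gm_other=1.0, a_gm_target=1.0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass
class SubjectData:
    """One simulated subject: truth, observed activity, masks, parcellation."""

    meta: SubjectMeta
    load: float
    truth: Image3D  # SUV-unit piecewise-constant truth
    observed: Image3D  # activity units (kBq/mL): blurred, noisy, dose-scaled
    masks: dict[str, Image3D]
    parcellation: Parcellation  # with the target VOI inserted
    voi: Image3D


@dataclass
class CohortDataset:
    """A simulated cohort plus its full generative record."""

    subjects: list[SubjectData]
    histology: pd.DataFrame  # subject_id, h6cnpib_pct, h4g8_pct
    cohort_spec: CohortSpec
    phantom_spec: PhantomSpec

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.meta.subject_id,
                    "weight_kg": s.meta.weight_kg,
                    "dose_kbq": s.meta.dose_kbq,
                }
                for s in self.subjects
            ]
        )

    @property
    def generative_record(self) -> dict:
        return {
            "cohort_spec": asdict(self.cohort_spec),
            "phantom_spec": asdict(self.phantom_spec),
            "loads": [s.load for s in self.subjects],
        }


def _subject_meta(i: int) -> SubjectMeta:
    # deterministic, mildly varied scaling metadata; SUVR is invariant to it
    return SubjectMeta(
        subject_id=f"sim{i + 1:02d}",
        weight_kg=65.0 + 2.0 * i,
        dose_kbq=480.0 + 15.0 * i,
    )


def simulate_cohort(
    cspec: CohortSpec, pspec: PhantomSpec | None = None
) -> CohortDataset:
    """Generate a full simulated cohort.

    Draw order (single generator seeded with ``cspec.seed``): all loads
    first, then per-subject scan-noise fields in subject order, then the two
    histology error vectors.  Zero-variance stages draw nothing, so e.g.
    ``eta = 0`` does not shift the histology draws of a different run.
    """
    if pspec is None:
        pspec = PhantomSpec()
    rng = np.random.default_rng(cspec.seed)
    loads = rng.uniform(cspec.load_range[0], cspec.load_range[1], cspec.n_subjects)
    psf = PSFModel(fwhm_mm=tuple(cspec.fwhm_mm))

    subjects: list[SubjectData] = []
    for i, load in enumerate(loads):
        thickness = max(
            cspec.d_min_mm,
            pspec.gm_thickness_mm - cspec.atrophy_mm_per_load * load,
        )
        spec_i = replace(
            pspec,
            gm_thickness_mm=thickness,
            a_gm_target=cspec.beta0 + cspec.beta1 * load,
        )
        truth, masks, parc = build_phantom(spec_i)
        observed_suv = simulate_scan(
            truth, psf, cspec.eta, rng, brain=masks["brain"]
        )
        meta = _subject_meta(i)
        # truth is in SUV units; store the observation as raw activity so the
        # pipeline exercises the SUV scaling step
        observed_activity = observed_suv.with_data(
            observed_suv.data * (meta.dose_kbq / meta.weight_kg)
        )
        voi = target_voi_mask(spec_i, parc)
        parc_with_voi = insert_voi_into_parcellation(parc, voi)
        subjects.append(
            SubjectData(
                meta=meta,
                load=float(load),
                truth=truth,
                observed=observed_activity,
                masks=masks,
                parcellation=parc_with_voi,
                voi=voi,
            )
        )

    if cspec.histology_sd > 0:
        eps6 = rng.normal(0.0, cspec.histology_sd, cspec.n_subjects)
        eps4 = rng.normal(0.0, cspec.histology_sd, cspec.n_subjects)
    else:
        eps6 = eps4 = np.zeros(cspec.n_subjects)
    h6 = np.maximum(cspec.gamma6 * loads + eps6, 0.01)
    h4 = np.maximum(cspec.gamma4 * loads + eps4, 0.01)
    histology = pd.DataFrame(
        {
            "subject_id": [s.meta.subject_id for s in subjects],
            "h6cnpib_pct": h6,
            "h4g8_pct": h4,
        }
    )
    return CohortDataset(
        subjects=subjects,
        histology=histology,
        cohort_spec=cspec,
        phantom_spec=pspec,
    )
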