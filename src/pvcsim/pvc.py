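"""Partial-volume correction: Meltzer, modified Muller-Gartner, GTM and RBV.

All three corrections share one forward model: the observed PET image O is the
true activity T convolved with the scanner point-spread function h,

    O = T (x) h.

* **Meltzer** is the two-compartment brain-vs-CSF correction.  It divides the
  observed image by the smoothed whole-brain tissue mask, compensating
  spill-out of activity from brain tissue into CSF/background; it does not
  model heterogeneity within tissue.

* **modified Muller-Gartner (mMG)** corrects cortical GM for
  cross-contamination with WM.  An estimate of the WM activity (two-region
  GTM by default, or an eroded-WM mean) is forward-smoothed and subtracted,
  and the remainder is divided by the smoothed GM mask.  CSF is assumed to
  carry zero activity, so it enters only through mask exclusion.

* **GTM** (geometric transfer matrix) solves for partial-volume-free regional
  means: omega_ij is the mean over region i of the smoothed mask of region j,
  and Omega t = o is solved directly for the true means t given observed
  regional means o.

* **RBV** (region-based voxel-wise) extends GTM to a voxel-level image:
  a piecewise-constant synthetic image s built from the GTM means is used to
  rescale the observation voxelwise, C = O * s / (s (x) h).

Each correction returns a :class:`PVCResult` holding the corrected image, a
validity mask of voxels where the correction is defined, and a parameter
record sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, ndimage

from .images import (
    GridMismatchError,
    Image3D,
    Parcellation,
    check_same_grid,
    write_image,
)
from .psf import PSFModel, convolve_array, make_kernel, smooth_mask

logger = logging.getLogger(__name__)

#: condition number of the transfer matrix above which a warning is emitted
GTM_COND_WARN = 1e4


@dataclass
class RegionalMeans:
    """GTM solution: observed and corrected regional means plus the matrix.

    ``omega[i, j]`` is the fraction of region j's (unit) activity observed,
    after smoothing, inside region i; rows therefore sum to at most one.
    """

    regions: list[int]
    observed: np.ndarray
    true_means: np.ndarray
    omega: np.ndarray
    cond: float

    def __post_init__(self) -> None:
        n = len(self.regions)
        if self.omega.shape != (n, n):
            raise ValueError("omega must be square, one row per region")
        if np.any(self.omega < -1e-9) or np.any(self.omega > 1 + 1e-9):
            raise ValueError("omega entries outside [0, 1]")
        if np.any(self.omega.sum(axis=1) > 1 + 1e-9):
            raise ValueError("omega row sums exceed 1")

    def as_dict(self) -> dict[int, float]:
        return {lab: float(t) for lab, t in zip(self.regions, self.true_means)}


@dataclass
class PVCResult:
    """A corrected image, its validity mask, and the parameters that made it."""

    corrected: Image3D
    validity: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.validity.shape != self.corrected.data.shape:
            raise ValueError("validity shape mismatch")
        self.validity = self.validity.astype(np.uint8)
        valid_vals = self.corrected.data[self.validity.astype(bool)]
        if valid_vals.size and not np.all(np.isfinite(valid_vals)):
            raise ValueError("non-finite corrected values inside validity mask")

    def write(self, prefix: str | Path) -> None:
        """Write corrected image, validity mask and a JSON parameter sidecar."""
        prefix = Path(prefix)
        write_image(self.corrected, prefix.with_suffix(".nii"))
        write_image(
            Image3D(data=self.validity, affine=self.corrected.affine),
            Path(str(prefix) + "_validity.nii"),
        )
        sidecar = {"method": self.method, **_jsonable(self.params)}
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def no_correction(suv: Image3D, brain: Image3D) -> PVCResult:
    """Uncorrected pass-through with the brain mask as validity."""
    check_same_grid(suv, brain)
    return PVCResult(
        corrected=suv.with_data(suv.data.astype(np.float64)),
        validity=brain.data.astype(np.uint8),
        method="none",
        params={},
    )


def meltzer_correct(
    suv: Image3D, brain: Image3D, psf: PSFModel, tau: float = 0.1
) -> PVCResult:
    """Meltzer two-compartment correction: O / (M_brain (x) h).

    Defined at brain voxels where the smoothed mask is at least ``tau``
    (default 0.1, i.e. voxels whose observed signal is >= 90 % spill-in are
    excluded); elsewhere the output is 0 with validity 0.
    """
    if not (0 < tau <= 1):
        raise ValueError("tau must lie in (0, 1]")
    check_same_grid(suv, brain)
    smoothed = smooth_mask(brain, psf)
    valid = (brain.data.astype(bool)) & (smoothed >= tau)
    if not valid.any():
        raise ValueError("Meltzer correction has an empty valid set")
    out = np.zeros(suv.data.shape, dtype=np.float64)
    out[valid] = suv.data[valid] / smoothed[valid]
    return PVCResult(
        corrected=suv.with_data(out),
        validity=valid,
        method="meltzer",
        params={"fwhm_mm": list(psf.fwhm_mm), "tau": tau},
    )


def _region_smoothed_masks(
    parc: Parcellation, psf: PSFModel, voxel_size_mm
) -> dict[int, np.ndarray]:
    kernel = make_kernel(psf, voxel_size_mm)
    out = {}
    for lab in parc.labels:
        out[lab] = convolve_array((parc.labelmap == lab).astype(np.float64), kernel)
    return out


def gtm_solve(
    suv: Image3D,
    parc: Parcellation,
    psf: PSFModel,
    smoothed_masks: dict[int, np.ndarray] | None = None,
) -> RegionalMeans:
    """Geometric-transfer-matrix estimate of partial-volume-free region means.

    Builds omega_ij as the mean of the smoothed mask of region j over the
    voxels of region i, the observed vector o as the regional means of the
    input, and solves Omega t = o by a direct dense solve (no nonnegativity
    constraint).  The condition number is recorded and a warning emitted
    above ``GTM_COND_WARN``.

    ``smoothed_masks`` may carry precomputed smoothed region masks (keyed by
    label) to share work across corrections using the same PSF.
    """
    if parc.labelmap.shape != suv.data.shape or not np.allclose(
        parc.affine, suv.affine, atol=1e-4
    ):
        raise GridMismatchError("parcellation and image are on different grids")
    labels = parc.labels
    if not labels:
        raise ValueError("parcellation has no regions")
    if smoothed_masks is None:
        smoothed_masks = _region_smoothed_masks(parc, psf, suv.voxel_size_mm)
    n = len(labels)
    omega = np.empty((n, n), dtype=np.float64)
    observed = np.empty(n, dtype=np.float64)
    region_index = {lab: np.flatnonzero(parc.labelmap.ravel() == lab) for lab in labels}
    flat_suv = suv.data.ravel().astype(np.float64)
    for i, lab_i in enumerate(labels):
        idx = region_index[lab_i]
        if idx.size == 0:
            raise ValueError(f"region {lab_i} is empty")
        observed[i] = flat_suv[idx].mean()
        for j, lab_j in enumerate(labels):
            omega[i, j] = smoothed_masks[lab_j].ravel()[idx].mean()
    cond = float(np.linalg.cond(omega))
    if not np.isfinite(cond):
        raise ValueError("singular transfer matrix")
    if cond > GTM_COND_WARN:
        warnings.warn(
            f"transfer matrix badly conditioned (cond={cond:.3g})", stacklevel=2
        )
    true_means = linalg.solve(omega, observed)
    return RegionalMeans(
        regions=labels, observed=observed, true_means=true_means, omega=omega, cond=cond
    )


def _wm_mean_by_erosion(
    suv: Image3D, wm: Image3D, psf: PSFModel
) -> float | None:
    """Mean over WM eroded by one PSF FWHM (None when erosion empties WM)."""
    fwhm = float(np.mean(psf.fwhm_mm))
    if fwhm == 0:
        core = wm.data.astype(bool)
    else:
        dist = ndimage.distance_transform_edt(
            wm.data.astype(bool), sampling=wm.voxel_size_mm
        )
        core = dist >= fwhm
    if not core.any():
        return None
    return float(suv.data[core].mean())


def mmg_correct(
    suv: Image3D,
    gm: Image3D,
    wm: Image3D,
    psf: PSFModel,
    tau_gm: float = 0.1,
    wm_mode: str = "gtm2",
    wm_activity: float | None = None,
    clamp_negative: bool = False,
) -> PVCResult:
    """Modified Muller-Gartner GM correction.

    C(x) = [O(x) - A_WM * (M_WM (x) h)(x)] / (M_GM (x) h)(x) at GM voxels
    where the smoothed GM mask is at least ``tau_gm``.  The WM activity
    estimate A_WM comes from a two-region GTM on {GM, WM} (``wm_mode="gtm2"``,
    the default), from the mean over WM eroded by one FWHM
    (``wm_mode="erosion"``, falling back to gtm2 when erosion empties the
    mask), or from an explicit ``wm_activity`` override.

    Negative corrected values are retained (they are data) and counted in the
    parameter record; ``clamp_negative`` sets them to zero for sensitivity
    analysis.
    """
    if not (0 < tau_gm <= 1):
        raise ValueError("tau_gm must lie in (0, 1]")
    if wm_mode not in ("gtm2", "erosion"):
        raise ValueError(f"unknown wm_mode {wm_mode!r}")
    check_same_grid(suv, gm, wm)
    if np.any(gm.data.astype(bool) & wm.data.astype(bool)):
        raise ValueError("GM and WM masks overlap")

    sgm = smooth_mask(gm, psf)
    wm_empty = not wm.data.any()
    swm = smooth_mask(wm, psf) if not wm_empty else np.zeros_like(sgm)

    wm_source = "fixed"
    if wm_empty:
        # degenerate case: reduces to a GM-restricted Meltzer-style division
        a_wm = 0.0
        wm_source = "empty-wm"
    elif wm_activity is not None:
        a_wm = float(wm_activity)
    else:
        a_wm = None
        if wm_mode == "erosion":
            a_wm = _wm_mean_by_erosion(suv, wm, psf)
            wm_source = "erosion"
        if a_wm is None:  # gtm2, or erosion fallback
            labelmap = gm.data.astype(np.int16) + 2 * wm.data.astype(np.int16)
            parc2 = Parcellation(
                labelmap=labelmap,
                affine=suv.affine,
                region_table={1: "gm", 2: "wm"},
            )
            sol = gtm_solve(
                suv, parc2, psf, smoothed_masks={1: sgm, 2: swm}
            )
            a_wm = float(sol.true_means[1])
            wm_source = "gtm2"

    valid = gm.data.astype(bool) & (sgm >= tau_gm)
    if not valid.any():
        raise ValueError("mMG correction has an empty valid GM set")
    out = np.zeros(suv.data.shape, dtype=np.float64)
    out[valid] = (suv.data[valid] - a_wm * swm[valid]) / sgm[valid]
    n_negative = int((out[valid] < 0).sum())
    if n_negative:
        logger.info("mMG produced %d negative corrected voxel(s)", n_negative)
    if clamp_negative:
        out[valid & (out < 0)] = 0.0
    return PVCResult(
        corrected=suv.with_data(out),
        validity=valid,
        method="mmg",
        params={
            "fwhm_mm": list(psf.fwhm_mm),
            "tau_gm": tau_gm,
            "wm_mode": wm_mode,
            "wm_activity": a_wm,
            "wm_activity_source": wm_source,
            "n_negative": n_negative,
            "clamp_negative": clamp_negative,
        },
    )


def rbv_correct(
    suv: Image3D,
    parc: Parcellation,
    psf: PSFModel,
    eps: float | None = None,
    smoothed_masks: dict[int, np.ndarray] | None = None,
) -> PVCResult:
    """Region-based voxel-wise correction.

    Solves the GTM for regional means t, builds the piecewise-constant
    synthetic image s = sum_j t_j M_j, and rescales the observation,
    C = O * s / (s (x) h), at labelled voxels where the smoothed synthetic
    image is at least ``eps`` (default 1e-6 of the synthetic maximum).
    Voxels outside every region pass through uncorrected with validity 0.
    """
    sol = gtm_solve(suv, parc, psf, smoothed_masks=smoothed_masks)
    synthetic = np.zeros(suv.data.shape, dtype=np.float64)
    for lab, t in zip(sol.regions, sol.true_means):
        synthetic[parc.labelmap == lab] = t
    if not synthetic.any():
        raise ValueError("all-zero synthetic image")
    if eps is None:
        eps = 1e-6 * float(np.abs(synthetic).max())
    kernel = make_kernel(psf, suv.voxel_size_mm)
    smoothed_syn = convolve_array(synthetic, kernel)
    labelled = parc.labelmap > 0
    valid = labelled & (smoothed_syn >= eps)
    out = suv.data.astype(np.float64).copy()  # out-of-parcellation pass-through
    out[valid] = suv.data[valid] * synthetic[valid] / smoothed_syn[valid]
    out[labelled & ~valid] = 0.0
    return PVCResult(
        corrected=suv.with_data(out),
        validity=valid,
        method="rbv",
        params={
            "fwhm_mm": list(psf.fwhm_mm),
            "eps": float(eps),
            "gtm_cond": sol.cond,
            "gtm_means": sol.as_dict(),
        },
    )


def insert_voi_into_parcellation(parc: Parcellation, voi: Image3D) -> Parcellation:
    """Split a target VOI out of an existing parcellation.

    For every original label L that intersects the VOI, the intersection
    becomes a new label named ``<name>+voi`` and is removed from L; labels
    fully swallowed by the VOI are dropped from the region table.  Coverage
    and mutual exclusivity are preserved by construction; the total labelled
    voxel count is conserved.
    """
    if parc.labelmap.shape != voi.data.shape or not np.allclose(
        parc.affine, voi.affine, atol=1e-4
    ):
        raise GridMismatchError("VOI and parcellation are on different grids")
    voi_mask = voi.data.astype(bool)
    overlapped = sorted(
        set(int(v) for v in np.unique(parc.labelmap[voi_mask])) - {0}
    )
    if not overlapped:
        raise ValueError("VOI does not intersect any parcellation region")
    labelmap = parc.labelmap.copy()
    table = dict(parc.region_table)
    next_label = max(parc.labels) + 1
    for lab in overlapped:
        sub = (parc.labelmap == lab) & voi_mask
        labelmap[sub] = next_label
        table[next_label] = f"{parc.region_table[lab]}+voi"
        if not ((parc.labelmap == lab) & ~voi_mask).any():
            del table[lab]
        next_label += 1
    return Parcellation(labelmap=labelmap, affine=parc.affine.copy(), region_table=table)
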