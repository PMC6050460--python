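"""GM-restricted VOI sampling and SUVR computation.

The target VOI is intersected with the GM tissue mask before sampling, so the
PET measure mimics a pathology-load analysis performed exclusively in grey
matter.  SUVR normalises the VOI mean to the cerebellar-GM mean sampled from
the *same* corrected image, so numerator and denominator are equivalently
corrected (or equivalently uncorrected) by construction.

Means ignore voxels outside a correction's validity mask rather than
zero-filling them; the voxel counts actually used are reported so that a
shrinking valid set is visible in the output tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import Image3D, check_same_grid
from .pvc import PVCResult

#: default minimum number of GM voxels a VOI must retain
MIN_VOI_VOXELS = 10


@dataclass(frozen=True)
class SUVRRecord:
    """One subject x method SUVR measurement with its provenance counts."""

    subject_id: str
    method: str
    voi_mean: float
    ref_mean: float
    suvr: float
    n_voi_voxels: int
    n_ref_voxels: int

    def __post_init__(self) -> None:
        if not self.ref_mean > 0:
            raise ValueError("reference mean must be positive")
        if abs(self.suvr - self.voi_mean / self.ref_mean) > 1e-12 * max(1.0, abs(self.suvr)):
            raise ValueError("suvr must equal voi_mean / ref_mean")


def restrict_voi_to_gm(
    voi: Image3D, gm: Image3D, min_voxels: int = MIN_VOI_VOXELS
) -> Image3D:
    """Voxelwise AND of a VOI with the GM mask.

    Raises when fewer than ``min_voxels`` GM voxels remain — a guard against
    degenerate autopsy-style VOIs that barely touch cortex.
    """
    check_same_grid(voi, gm)
    out = (voi.data.astype(bool) & gm.data.astype(bool)).astype(np.uint8)
    n = int(out.sum())
    if n < min_voxels:
        raise ValueError(
            f"VOI retains only {n} GM voxel(s); minimum is {min_voxels}"
        )
    return Image3D(data=out, affine=voi.affine.copy())


def region_mean(result: PVCResult | Image3D, mask: Image3D) -> tuple[float, int]:
    """Mean of values over ``mask`` intersected with the validity mask.

    Accepts either a :class:`PVCResult` (whose validity restricts the
    sample) or a plain :class:`Image3D` (optionally carrying its own
    validity).  Returns ``(mean, n_voxels_used)``.
    """
    if isinstance(result, PVCResult):
        img = result.corrected
        validity = result.validity.astype(bool)
    else:
        img = result
        validity = (
            np.ones(img.data.shape, dtype=bool)
            if img.validity is None
            else img.validity.astype(bool)
        )
    check_same_grid(img, mask)
    effective = mask.data.astype(bool) & validity
    n = int(effective.sum())
    if n == 0:
        raise ValueError("empty effective mask (mask does not meet validity)")
    return float(img.data[effective].mean()), n


def compute_suvr(
    result: PVCResult,
    voi_gm: Image3D,
    cereb_gm: Image3D,
    subject_id: str = "",
) -> SUVRRecord:
    """SUVR = mean over the GM-restricted VOI / mean over cerebellar GM."""
    voi_mean, n_voi = region_mean(result, voi_gm)
    ref_mean, n_ref = region_mean(result, cereb_gm)
    if ref_mean <= 0:
        raise ValueError(f"non-positive cerebellar reference mean ({ref_mean})")
    return SUVRRecord(
        subject_id=subject_id,
        method=result.method,
        voi_mean=voi_mean,
        ref_mean=ref_mean,
        suvr=voi_mean / ref_mean,
        n_voi_voxels=n_voi,
        n_ref_voxels=n_ref,
    )
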