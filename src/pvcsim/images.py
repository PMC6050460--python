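"""Voxel-grid containers, NIfTI I/O, frame averaging and SUV scaling.

The data model is deliberately small: an :class:`Image3D` is a scalar field on a
regular voxel grid with a 4x4 grid-to-world affine; binary masks and integer
parcellations live on the same grid.  All partial-volume operations downstream
require inputs on an *identical* grid — there is no implicit resampling, and a
:class:`GridMismatchError` is raised instead (registration and resampling are
assumed to have happened upstream).

Conventions
-----------
* voxel indices are 0-based; all geometry is expressed in world millimetres via
  the affine;
* masks are stored as 8-bit integers in {0, 1}; parcellation label maps as
  16-bit integers with 0 meaning "outside every region";
* SUV scaling uses dose in kBq, body weight in kg and activity in kBq/mL, with
  the conventional 1 g/mL tissue density applied silently (and logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: absolute tolerance (mm) for declaring two affines "the same grid"
GRID_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share dims and affine; no implicit resampling."""


class CoverageError(ValueError):
    """A parcellation covers less of the brain than the configured minimum."""


def _affine_voxel_sizes(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Image3D:
    """Scalar field on a regular 3-D voxel grid.

    Parameters
    ----------
    data:
        3-D array of voxel values (activity in kBq/mL, or unitless SUV).
    affine:
        4x4 invertible grid-to-world map (NIfTI convention, mm).
    validity:
        Optional per-voxel defined/undefined flag.  Where present, only
        voxels with ``validity != 0`` are considered defined; undefined
        voxels are ignored by every mean/sampling operation downstream.
    """

    data: np.ndarray
    affine: np.ndarray
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires a 3-D array, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(_affine_voxel_sizes(self.affine) > 0):
            raise ValueError("non-positive voxel sizes in affine")
        if self.validity is not None:
            self.validity = np.asarray(self.validity)
            if self.validity.shape != self.data.shape:
                raise ValueError("validity shape does not match data")
        if np.issubdtype(self.data.dtype, np.floating):
            defined = (
                self.data
                if self.validity is None
                else self.data[self.validity.astype(bool)]
            )
            if defined.size and not np.all(np.isfinite(defined)):
                raise ValueError("non-finite values among defined voxels")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(_affine_voxel_sizes(self.affine))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, validity: np.ndarray | None = None) -> "Image3D":
        """New image on this grid with different voxel values."""
        return Image3D(data=data, affine=self.affine.copy(), validity=validity)


def same_grid(a: Image3D, b: Image3D, atol: float = GRID_ATOL) -> bool:
    return a.data.shape == b.data.shape and np.allclose(a.affine, b.affine, atol=atol)


def check_same_grid(*images: Image3D) -> None:
    ref = images[0]
    for img in images[1:]:
        if not same_grid(ref, img):
            raise GridMismatchError(
                f"grids differ: dims {ref.data.shape} vs {img.data.shape} "
                "or affines disagree beyond tolerance"
            )


@dataclass
class Image4D:
    """Dynamic acquisition: ordered frames on one shared grid.

    ``frame_windows`` holds the (start_min, end_min) acquisition window of
    each frame; windows must be increasing and non-overlapping.
    """

    frames: list[Image3D]
    frame_windows: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("Image4D requires at least one frame")
        if len(self.frames) != len(self.frame_windows):
            raise ValueError("one window per frame required")
        check_same_grid(*self.frames)
        prev_end = -np.inf
        for start, end in self.frame_windows:
            if end <= start:
                raise ValueError(f"degenerate frame window ({start}, {end})")
            if start < prev_end:
                raise ValueError("frame windows overlap or are out of order")
            prev_end = end


def frame_average(dyn: Image4D, window: tuple[float, float]) -> Image3D:
    """Duration-weighted voxelwise mean of frames fully inside ``window``.

    A frame contributes iff its acquisition window lies entirely within the
    requested window; partially overlapping frames are excluded (frames are
    treated as indivisible acquisitions — no fractional-frame weighting).
    """
    start, end = window
    included: list[tuple[Image3D, float]] = []
    for img, (fs, fe) in zip(dyn.frames, dyn.frame_windows):
        if fs >= start and fe <= end:
            included.append((img, fe - fs))
    if not included:
        raise ValueError(f"no frame fully inside window ({start}, {end}) min")
    total = sum(dur for _, dur in included)
    acc = np.zeros(included[0][0].data.shape, dtype=np.float64)
    for img, dur in included:
        acc += img.data.astype(np.float64) * dur
    return included[0][0].with_data(acc / total)


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level scaling metadata: body weight (kg) and injected dose (kBq)."""

    subject_id: str
    weight_kg: float
    dose_kbq: float

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValueError("weight must be positive")
        if not self.dose_kbq > 0:
            raise ValueError("dose must be positive")


def to_suv(img: Image3D, meta: SubjectMeta) -> Image3D:
    """Scale an activity image (kBq/mL) to SUV: voxel * weight / dose.

    A tissue density of 1 g/mL is assumed so that kBq/mL * kg / kBq is
    dimensionless; the assumption is logged for provenance.
    """
    logger.debug(
        "SUV scaling for %s: weight=%.3f kg, dose=%.3f kBq, density 1 g/mL assumed",
        meta.subject_id,
        meta.weight_kg,
        meta.dose_kbq,
    )
    return img.with_data(
        img.data.astype(np.float64) * (meta.weight_kg / meta.dose_kbq),
        validity=None if img.validity is None else img.validity.copy(),
    )


# ---------------------------------------------------------------------------
# masks and parcellations
# ---------------------------------------------------------------------------


def make_mask(data: np.ndarray, affine: np.ndarray) -> Image3D:
    """Binary mask as an Image3D with uint8 values in {0, 1}."""
    arr = np.asarray(data)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask values must be 0/1")
    return Image3D(data=arr.astype(np.uint8), affine=affine)


@dataclass
class Parcellation:
    """Non-overlapping integer-labelled regions spanning the brain.

    ``labelmap`` assigns one 16-bit label per voxel (0 = outside all
    regions); ``region_table`` maps every nonzero label to a region name.
    Mutual exclusivity is guaranteed by construction (one label per voxel).
    """

    labelmap: np.ndarray
    affine: np.ndarray
    region_table: dict[int, str]

    def __post_init__(self) -> None:
        self.labelmap = np.asarray(self.labelmap)
        if self.labelmap.ndim != 3:
            raise ValueError("labelmap must be 3-D")
        if not np.issubdtype(self.labelmap.dtype, np.integer):
            raise ValueError("labelmap must be integer typed")
        if self.labelmap.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.labelmap = self.labelmap.astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(int(v) for v in np.unique(self.labelmap)) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present but not in region_table")
        empty = set(self.region_table) - present
        if empty:
            raise ValueError(f"region_table lists empty regions {sorted(empty)}")

    @property
    def labels(self) -> list[int]:
        return sorted(self.region_table)

    def region_sizes(self) -> dict[int, int]:
        return {lab: int((self.labelmap == lab).sum()) for lab in self.labels}

    def as_image(self) -> Image3D:
        return Image3D(data=self.labelmap, affine=self.affine)


def binarize_labels(
    parc: Parcellation, labels, require_nonempty: bool = False
) -> Image3D:
    """Union binary mask of the given parcellation labels.

    Labels absent from the parcellation are tolerated with a warning; an
    empty label set (or an all-absent one) yields an all-zero mask, which is
    an error only when ``require_nonempty`` is set.
    """
    wanted = set(int(lab) for lab in labels)
    absent = wanted - set(parc.region_table)
    if absent:
        warnings.warn(f"labels {sorted(absent)} absent from parcellation", stacklevel=2)
    mask = np.isin(parc.labelmap, sorted(wanted)).astype(np.uint8)
    if mask.sum() == 0:
        if require_nonempty:
            raise ValueError("binarize_labels produced an empty mask")
        warnings.warn("binarize_labels produced an empty mask", stacklevel=2)
    return Image3D(data=mask, affine=parc.affine.copy())


@dataclass(frozen=True)
class ParcellationReport:
    coverage: float
    leakage: int
    region_sizes: dict[int, int]


def validate_parcellation(
    parc: Parcellation, brain: Image3D, min_coverage: float = 0.999
) -> ParcellationReport:
    """Check that a parcellation tiles the brain mask.

    Reports the fraction of brain voxels carrying a nonzero label
    (coverage), the number of labelled voxels outside the brain (leakage,
    warned about but tolerated) and per-region sizes.  Raises
    :class:`CoverageError` below ``min_coverage``.
    """
    if parc.labelmap.shape != brain.data.shape or not np.allclose(
        parc.affine, brain.affine, atol=GRID_ATOL
    ):
        raise GridMismatchError("parcellation and brain mask are on different grids")
    inside = brain.data.astype(bool)
    n_brain = int(inside.sum())
    if n_brain == 0:
        raise ValueError("empty brain mask")
    labelled = parc.labelmap > 0
    coverage = float((labelled & inside).sum() / n_brain)
    leakage = int((labelled & ~inside).sum())
    if leakage:
        warnings.warn(f"{leakage} labelled voxel(s) outside the brain mask", stacklevel=2)
    report = ParcellationReport(
        coverage=coverage, leakage=leakage, region_sizes=parc.region_sizes()
    )
    if coverage < min_coverage:
        raise CoverageError(
            f"parcellation covers {coverage:.4%} of the brain, below {min_coverage:.4%}"
        )
    return report


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> Image3D:
    """Load a 3-D NIfTI-1 volume.

    Integer-typed files (masks, label maps) are loaded without value change;
    floating files are loaded as float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)
    return Image3D(data=data, affine=np.asarray(img.affine, dtype=float))


def write_image(img: Image3D, path: str | Path) -> None:
    """Write an image/mask to NIfTI-1; float data stored as float32."""
    data = img.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    nifti = nib.Nifti1Image(data, img.affine)
    nifti.header.set_zooms(img.voxel_size_mm)
    nib.save(nifti, str(path))


def read_parcellation(path: str | Path, region_table: dict[int, str] | None = None) -> Parcellation:
    """Load a label map; region names default to ``region_<label>``."""
    img = read_image(path)
    if not np.issubdtype(img.data.dtype, np.integer):
        rounded = np.rint(img.data)
        if not np.allclose(img.data, rounded):
            raise ValueError("parcellation file has non-integer values")
        img = Image3D(data=rounded.astype(np.int16), affine=img.affine)
    present = sorted(set(int(v) for v in np.unique(img.data)) - {0})
    if region_table is None:
        region_table = {lab: f"region_{lab}" for lab in present}
    return Parcellation(labelmap=img.data, affine=img.affine, region_table=region_table)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    write_image(parc.as_image(), path)
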