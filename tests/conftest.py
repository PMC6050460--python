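"""Shared fixtures: small grids, phantoms, and a cached default phantom."""

from __future__ import annotations

import numpy as np
import pytest

from pvcsim.images import Image3D, Parcellation, make_mask
from pvcsim.phantom import PhantomSpec, build_phantom, target_voi_mask
from pvcsim.psf import PSFModel


def grid_affine(voxel=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    affine = np.eye(4)
    for k in range(3):
        affine[k, k] = voxel[k]
        affine[k, 3] = origin[k]
    return affine


@pytest.fixture
def unit_affine() -> np.ndarray:
    return grid_affine()


@pytest.fixture(scope="session")
def default_phantom():
    """The default AD-like phantom (96^3, 2 mm, GM target 2.5)."""
    spec = PhantomSpec()
    truth, masks, parc = build_phantom(spec)
    return spec, truth, masks, parc


@pytest.fixture(scope="session")
def default_voi(default_phantom):
    spec, _, _, parc = default_phantom
    return target_voi_mask(spec, parc)


@pytest.fixture(scope="session")
def scanner_psf() -> PSFModel:
    return PSFModel.isotropic(6.0)


def make_slab_phantom(dims=(32, 32, 32), voxel=2.0, a_gm=2.0, a_wm=1.5, gm_lo=16, gm_hi=18):
    """Flat two-compartment phantom: WM half-space under a GM slab, CSF above.

    Returns (suv truth image, gm mask, wm mask).  The slab spans z indices
    [gm_lo, gm_hi); WM fills z < gm_lo.
    """
    affine = grid_affine((voxel, voxel, voxel))
    z = np.arange(dims[2])
    wm = np.zeros(dims, dtype=np.uint8)
    gm = np.zeros(dims, dtype=np.uint8)
    wm[:, :, z < gm_lo] = 1
    gm[:, :, (z >= gm_lo) & (z < gm_hi)] = 1
    truth = a_wm * wm.astype(float) + a_gm * gm.astype(float)
    return (
        Image3D(data=truth, affine=affine),
        make_mask(gm, affine),
        make_mask(wm, affine),
    )


def toy_parcellation(labelmap: np.ndarray, affine: np.ndarray) -> Parcellation:
    labels = sorted(set(int(v) for v in np.unique(labelmap)) - {0})
    return Parcellation(
        labelmap=labelmap.astype(np.int16),
        affine=affine,
        region_table={lab: f"r{lab}" for lab in labels},
    )
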