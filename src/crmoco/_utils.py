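"""Shared low-level helpers: seeding, NIfTI i/o, image warping.

Conventions used throughout the package:

* images are 2D ``(rows, cols)`` arrays; axis 0 is superior->inferior,
  axis 1 left->right; physical coordinate = index * pixel_size (mm)
* displacement fields are arrays of shape ``(2, rows, cols)`` in mm,
  stored in the *pull-back* convention: ``warp(img, disp)`` produces the
  image in the field's motion state by sampling the reference image at
  ``x + disp(x)`` for every grid point x of the state frame
"""

from __future__ import annotations

import zlib

import nibabel as nib
import numpy as np
from scipy import ndimage, sparse

# ---------------------------------------------------------------------------
# seeding


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic per-module child seed from one master seed."""
    h = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), h]).generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, name))


# ---------------------------------------------------------------------------
# NIfTI i/o (2D images stored as single-slice volumes, affine encodes mm)


def save_nifti(path, image: np.ndarray, pixel_size: float) -> None:
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    pixel_size = float(img.affine[0, 0])
    return arr, pixel_size


# ---------------------------------------------------------------------------
# warping


def warp_image(
    image: np.ndarray,
    disp_mm: np.ndarray,
    pixel_size: float,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Sample ``image`` at ``x + disp(x)``; order=0 for label maps."""
    ny, nx = image.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    coords = np.stack([yy + disp_mm[0] / pixel_size, xx + disp_mm[1] / pixel_size])
    return ndimage.map_coordinates(image, coords, order=order, mode="constant", cval=cval)


def warp_matrix(disp_mm: np.ndarray, pixel_size: float) -> sparse.csr_matrix:
    """Sparse bilinear-interpolation matrix implementing :func:`warp_image`
    (order=1, zero fill).  Its transpose is the exact adjoint warp."""
    _, ny, nx = disp_mm.shape
    n = ny * nx
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    py = (yy + disp_mm[0] / pixel_size).ravel()
    px = (xx + disp_mm[1] / pixel_size).ravel()
    y0 = np.floor(py).astype(int)
    x0 = np.floor(px).astype(int)
    fy = py - y0
    fx = px - x0
    rows, cols, vals = [], [], []
    ridx = np.arange(n)
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            yi = y0 + dy
            xi = x0 + dx
            ok = (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx)
            w = wy * wx
            ok &= w > 0
            rows.append(ridx[ok])
            cols.append((yi * nx + xi)[ok])
            vals.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return mat.tocsr()


def compose_fields(outer_mm: np.ndarray, inner_mm: np.ndarray, pixel_size: float) -> np.ndarray:
    """Compose two pull-back fields: the result warps the reference image by
    ``inner`` first, then ``outer`` (i.e. ``warp(warp(I, inner), outer)``).

    ``d(x) = outer(x) + inner(x + outer(x))`` with linear interpolation.
    """
    comp = np.empty_like(outer_mm)
    for c in range(2):
        comp[c] = outer_mm[c] + warp_image(inner_mm[c], outer_mm, pixel_size, order=1)
    return comp
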