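"""Parallel-beam projection geometry about a single tilt axis.

The tilt axis is the image y axis. A stage tilt by ``theta`` rotates the
object right-handedly about +y; the beam always runs along z, so the
projection at angle ``theta`` is the z-sum of the volume rotated by
``theta``. Back-projection is the reverse: each image is smeared along z
and rotated back by ``-theta``.

Both directions share one bilinear interpolation kernel in the (z, x)
plane, so reprojections of a back-projection are self-consistent — the
property the iterative alignment relies on. Because the kernel weights
depend only on the grid shape and the angle, both operators are cached as
per-angle sparse matrices acting on y columns at once; the dense
:func:`rotate_about_y` is the reference implementation of the same kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse

from .core import DensityMap, TiltSeries


def _inverse_coords(nz: int, nx: int, angle_deg: float):
    """Source (z, x) coordinates of each output voxel under rotation."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    Z, X = np.meshgrid(np.arange(nz) - cz, np.arange(nx) - cx, indexing="ij")
    # forward (right-handed about +y): x' = c*x + s*z ; z' = -s*x + c*z
    Xs = c * X - s * Z + cx
    Zs = s * X + c * Z + cz
    return Zs, Xs


def rotate_about_y(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a ``[z, y, x]`` volume right-handedly about the +y axis.

    Bilinear interpolation in the (z, x) plane about the grid center;
    regions rotated in from outside the grid are zero. The y axis is
    untouched, which keeps the operation a 2-D gather applied to all y
    rows at once.
    """
    vol = np.asarray(vol, dtype=np.float32)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    nz, ny, nx = vol.shape
    Zs, Xs = _inverse_coords(nz, nx, angle_deg)
    z0 = np.floor(Zs).astype(np.int64)
    x0 = np.floor(Xs).astype(np.int64)
    fz = (Zs - z0).astype(np.float32)
    fx = (Xs - x0).astype(np.float32)

    out = np.zeros((nz, nx, ny), dtype=np.float32)
    volT = np.ascontiguousarray(np.moveaxis(vol, 1, 2))  # (z, x, y)
    for dz in (0, 1):
        wz = (1 - fz) if dz == 0 else fz
        zi = z0 + dz
        ok_z = (zi >= 0) & (zi < nz)
        for dx in (0, 1):
            wx = (1 - fx) if dx == 0 else fx
            xi = x0 + dx
            ok = ok_z & (xi >= 0) & (xi < nx)
            w = np.where(ok, wz * wx, np.float32(0.0))
            out += w[:, :, None] * volT[np.clip(zi, 0, nz - 1),
                                        np.clip(xi, 0, nx - 1)]
    return np.moveaxis(out, 2, 1)


# ---------------------------------------------------------------------------
# cached sparse operators

_OP_CACHE: dict = {}


def _projection_operator(nz: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse ``(nx, nz*nx)`` operator: flattened (z, x) planes -> projection rows.

    Row x' of the result is the z-sum of the rotated volume, identical by
    construction to ``rotate_about_y(vol, angle).sum(axis=0)``.
    """
    key = (nz, nx, round(float(angle_deg), 9), "proj")
    if key in _OP_CACHE:
        return _OP_CACHE[key]
    Zs, Xs = _inverse_coords(nz, nx, angle_deg)
    z0 = np.floor(Zs).astype(np.int64)
    x0 = np.floor(Xs).astype(np.int64)
    fz, fx = Zs - z0, Xs - x0
    out_x = np.broadcast_to(np.arange(nx)[None, :], (nz, nx))
    rows, cols, vals = [], [], []
    for dz in (0, 1):
        wz = fz if dz else 1 - fz
        zi = z0 + dz
        ok_z = (zi >= 0) & (zi < nz)
        for dx in (0, 1):
            wx = fx if dx else 1 - fx
            xi = x0 + dx
            ok = ok_z & (xi >= 0) & (xi < nx)
            rows.append(out_x[ok])
            cols.append((zi * nx + xi)[ok])
            vals.append((wz * wx)[ok])
    op = sparse.csr_matrix(
        (np.concatenate(vals).astype(np.float32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx, nz * nx))
    _OP_CACHE[key] = op
    return op


def _backprojection_operator(nz: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse ``(nz*nx, nx)`` operator: image columns -> smeared, back-rotated volume.

    Identical by construction to ``rotate_about_y(smear(img), -angle)``:
    smearing makes the z interpolation collapse to a boundary weight, so
    each output voxel reads at most two image columns.
    """
    key = (nz, nx, round(float(angle_deg), 9), "back")
    if key in _OP_CACHE:
        return _OP_CACHE[key]
    Zs, Xs = _inverse_coords(nz, nx, -angle_deg)
    z0 = np.floor(Zs).astype(np.int64)
    x0 = np.floor(Xs).astype(np.int64)
    fz, fx = Zs - z0, Xs - x0
    wz_total = np.where((z0 >= 0) & (z0 < nz), 1 - fz, 0.0) \
        + np.where((z0 + 1 >= 0) & (z0 + 1 < nz), fz, 0.0)
    out_idx = np.arange(nz * nx).reshape(nz, nx)
    rows, cols, vals = [], [], []
    for dx in (0, 1):
        wx = fx if dx else 1 - fx
        xi = x0 + dx
        ok = (xi >= 0) & (xi < nx)
        rows.append(out_idx[ok])
        cols.append(xi[ok])
        vals.append((wz_total * wx)[ok])
    op = sparse.csr_matrix(
        (np.concatenate(vals).astype(np.float32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(nz * nx, nx))
    _OP_CACHE[key] = op
    return op


def project(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Line-integral projection of a ``[z, y, x]`` volume at one tilt angle."""
    vol = np.asarray(vol, dtype=np.float32)
    nz, ny, nx = vol.shape
    if abs(angle_deg) < 1e-12:
        return vol.sum(axis=0)
    op = _projection_operator(nz, nx, angle_deg)
    volT = np.ascontiguousarray(np.moveaxis(vol, 1, 2)).reshape(nz * nx, ny)
    return np.asarray((op @ volT).T)  # (y, x)


def project_map(density: DensityMap, angle_deg: float) -> np.ndarray:
    return project(density.data, angle_deg)


def shift_image(image: np.ndarray, shift_xy, subpixel: bool = True) -> np.ndarray:
    """Translate an image by ``(dx, dy)`` pixels (bilinear, zero fill).

    With ``subpixel=False`` the shift is rounded to whole pixels first — the
    behaviour of the early refinement rounds before the interpolation round.
    """
    dx, dy = float(shift_xy[0]), float(shift_xy[1])
    if not subpixel:
        dx, dy = round(dx), round(dy)
    if dx == 0 and dy == 0:
        return np.asarray(image, dtype=np.float32).copy()
    return ndimage.shift(np.asarray(image, dtype=np.float32), (dy, dx),
                         order=1, mode="constant", cval=0.0, prefilter=False)


def back_project_images(images: np.ndarray, angles: np.ndarray,
                        shifts: np.ndarray | None = None,
                        subpixel: bool = True) -> np.ndarray:
    """Back-project a stack of images into a cubic volume.

    Each image is translated by its alignment correction, smeared along the
    beam (z) direction and rotated back about the tilt axis; the result is
    the mean over images, so a single 0-degree view yields a volume whose
    every z slice equals that view.
    """
    images = np.asarray(images, dtype=np.float32)
    n, ny, nx = images.shape
    if ny != nx:
        raise ValueError("back-projection requires square images")
    if len(angles) != n:
        raise ValueError("one angle per image required")
    if shifts is not None:
        shifts = np.asarray(shifts, dtype=float)
        if not np.all(np.isfinite(shifts)):
            raise ValueError("shifts must be finite")
    acc = np.zeros((ny * nx, ny), dtype=np.float32)   # flattened (z, x) by y
    for i in range(n):
        img = images[i]
        if shifts is not None and np.any(shifts[i] != 0):
            img = shift_image(img, shifts[i], subpixel=subpixel)
        op = _backprojection_operator(ny, nx, angles[i])
        acc += op @ np.ascontiguousarray(img.T)        # (z*x, y)
    acc /= n
    return np.moveaxis(acc.reshape(ny, nx, ny), 1, 2).copy()


def reproject_series(vol: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Project a volume at every angle of a tilt schedule."""
    return np.stack([project(vol, a) for a in angles])


def tilt_silhouette(mask3d: np.ndarray, angle_deg: float,
                    thickness_ref: float = 4.0) -> np.ndarray:
    """2-D weight field of a 3-D mask seen at one tilt angle.

    The 3-D mask is projected along the beam; rays crossing at least
    ``thickness_ref`` voxels of mask get weight 1, shallower rays taper
    linearly to 0. This is the per-angle 2-D particle mask used for
    alignment and for 2-D SNR estimation.
    """
    proj = project(np.asarray(mask3d, dtype=np.float32), angle_deg)
    return np.clip(proj / float(thickness_ref), 0.0, 1.0)


def series_from_volume(density: DensityMap, angles: np.ndarray) -> TiltSeries:
    """Noise-free, jitter-free tilt series of a density map."""
    imgs = reproject_series(density.data, np.asarray(angles, float))
    return TiltSeries(imgs, np.asarray(angles, float), density.voxel_size)


__all__ = [
    "rotate_about_y", "project", "project_map", "shift_image",
    "back_project_images", "reproject_series", "tilt_silhouette",
    "series_from_volume",
]
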