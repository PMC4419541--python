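"""Soft masks and low-pass filters for the iterative refinement.

Two mask families drive the refinement: generous circular masks with a
cosine-tapered rim (round 1) and particle-shaped masks regenerated from the
evolving map (rounds 2-3). A particle mask is the map low-pass filtered to
40 angstroms and thresholded so the enclosed volume equals three times the
molecular mass converted to volume at standard protein density.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DensityMap, SoftMask, MASS_TO_VOLUME_A3_PER_DA


def lowpass(data: np.ndarray, cutoff_A: float, pixel_size: float) -> np.ndarray:
    """Gaussian low-pass filter with half-amplitude at ``1 / cutoff_A``.

    Works for 2-D images and 3-D volumes. The transfer function is
    ``exp(-f^2 / (2 sigma_f^2))`` with ``sigma_f`` chosen so the response is
    0.5 at the cutoff frequency.
    """
    if cutoff_A <= 2.0 * pixel_size:
        raise ValueError(
            f"cutoff {cutoff_A} A is at or beyond Nyquist for "
            f"{pixel_size} A pixels"
        )
    data = np.asarray(data, dtype=np.float32)
    f_c = 1.0 / cutoff_A
    sigma_f = f_c / np.sqrt(2.0 * np.log(2.0))
    freqs = [np.fft.fftfreq(n, d=pixel_size) for n in data.shape[:-1]]
    freqs.append(np.fft.rfftfreq(data.shape[-1], d=pixel_size))
    grids = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f2 = sum(g * g for g in grids)
    transfer = np.exp(-f2 / (2.0 * sigma_f**2))
    axes = tuple(range(data.ndim))
    out = np.fft.irfftn(np.fft.rfftn(data) * transfer, s=data.shape,
                        axes=axes)
    return out.astype(np.float32)


def lowpass_map(density: DensityMap, cutoff_A: float) -> DensityMap:
    return DensityMap(lowpass(density.data, cutoff_A, density.voxel_size),
                      density.voxel_size)


def _cosine_taper_from_binary(binary: np.ndarray, taper: float) -> np.ndarray:
    """Soften a binary region: cosine falloff over ``taper`` pixels outside."""
    if taper <= 0:
        return binary.astype(np.float32)
    dist = ndimage.distance_transform_edt(~binary)
    w = np.zeros(binary.shape, dtype=np.float32)
    w[binary] = 1.0
    rim = (~binary) & (dist <= taper)
    w[rim] = 0.5 * (1.0 + np.cos(np.pi * dist[rim] / taper))
    return w


def make_circular_mask(radius: float, taper: float, dims) -> SoftMask:
    """Circular (2-D) or spherical (3-D) soft mask about the grid center.

    Weight is 1 inside ``radius``, falls as a half-cosine over ``taper``
    pixels, and is 0 beyond ``radius + taper``.
    """
    dims = tuple(int(d) for d in dims)
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    if radius + taper > min(dims) / 2.0:
        raise ValueError("radius + taper exceeds half the grid size")
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in dims]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    r = np.sqrt(sum(g * g for g in grids))
    w = np.zeros(r.shape, dtype=np.float32)
    w[r <= radius] = 1.0
    if taper > 0:
        rim = (r > radius) & (r < radius + taper)
        w[rim] = 0.5 * (1.0 + np.cos(np.pi * (r[rim] - radius) / taper))
    return SoftMask(w, kind="circular", taper_width=float(taper))


def mass_to_volume_A3(mass_kda: float) -> float:
    """Molecular mass (kDa) to enclosed protein volume (cubic angstroms)."""
    return mass_kda * 1000.0 * MASS_TO_VOLUME_A3_PER_DA


def threshold_for_volume(data: np.ndarray, target_volume_A3: float,
                         voxel_size: float) -> float:
    """Intensity threshold whose super-level set encloses a target volume.

    Exact by construction: the threshold is read off the sorted intensity
    distribution (no bisection needed on a discrete grid).
    """
    flat = np.asarray(data, dtype=np.float32).ravel()
    if flat.max() - flat.min() < 1e-12 * max(1.0, abs(float(flat.max()))):
        raise ValueError("flat map: threshold cannot be bracketed")
    n_target = int(round(target_volume_A3 / voxel_size**3))
    if n_target < 1 or n_target >= flat.size:
        raise ValueError(
            f"target volume {target_volume_A3:.0f} A^3 maps to {n_target} "
            f"voxels, outside the grid of {flat.size}"
        )
    part = np.partition(flat, flat.size - n_target)
    return float(part[flat.size - n_target])


def make_particle_mask(density: DensityMap, lowpass_A: float = 40.0,
                       volume_multiple: float = 3.0, taper: float = 3.0,
                       mass_kda: float = 150.0) -> SoftMask:
    """Particle-shaped soft mask from a density map.

    The map is low-pass filtered (default 40 A), thresholded so the enclosed
    volume equals ``volume_multiple`` (default 3) times the protein volume
    of ``mass_kda``, then softened with a cosine taper.
    """
    if volume_multiple <= 0:
        raise ValueError("volume multiple must be positive")
    filt = lowpass(density.data, lowpass_A, density.voxel_size)
    target = volume_multiple * mass_to_volume_A3(mass_kda)
    thr = threshold_for_volume(filt, target, density.voxel_size)
    binary = filt > thr
    if not binary.any():
        binary = filt >= thr
    w = _cosine_taper_from_binary(binary, taper)
    return SoftMask(w, kind="particle", taper_width=float(taper))


__all__ = [
    "lowpass", "lowpass_map", "make_circular_mask", "make_particle_mask",
    "mass_to_volume_A3", "threshold_for_volume",
]
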