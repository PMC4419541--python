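"""Quality metrics: the mask-based SNR estimator and FSC resolution.

SNR follows the estimator ``SNR = (I_s - I_b) / N_b`` where ``I_s`` is the
mean intensity inside the particle mask, ``I_b`` the mean outside and
``N_b`` the standard deviation outside. "Inside" is the region where the
soft mask weight is at least 0.5.

Resolution is estimated from Fourier shell correlation between half-set
reconstructions (0.5 threshold for matched halves, 0.143 for the
gold-standard split where the raw, unaligned halves are reconstructed
independently) or between a map and a rasterized atomic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DensityMap, SoftMask, TiltSeries
from .masks import lowpass


@dataclass
class SNRReport:
    """Signal-to-noise report; ``snr = (I_s - I_b) / N_b`` by construction."""

    snr: float
    I_s: float
    I_b: float
    N_b: float
    mask_provenance: str = ""


def estimate_snr(data: np.ndarray, mask: SoftMask,
                 mask_provenance: str = "") -> SNRReport:
    """Mask-based SNR of an image or map.

    Raises when the background (outside) region is empty or has zero
    variance, since the estimator divides by the background deviation.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.shape != mask.weights.shape:
        raise ValueError("mask and data dimensions differ")
    inside = mask.inside
    outside = ~inside
    if not outside.any() or not inside.any():
        raise ValueError("mask must leave both inside and outside nonempty")
    I_s = float(data[inside].mean())
    I_b = float(data[outside].mean())
    N_b = float(data[outside].std())
    if N_b <= 0:
        raise ValueError("zero-variance background: SNR undefined")
    return SNRReport(snr=(I_s - I_b) / N_b, I_s=I_s, I_b=I_b, N_b=N_b,
                     mask_provenance=mask_provenance)


@dataclass
class FSCCurve:
    """Fourier shell correlation per radial shell of one Fourier voxel."""

    shell_frequencies: np.ndarray   # 1/A, strictly increasing
    correlations: np.ndarray        # dimensionless, clipped to [-1, 1]
    shell_width: float              # 1/A

    def __post_init__(self):
        self.shell_frequencies = np.asarray(self.shell_frequencies, float)
        self.correlations = np.asarray(self.correlations, float)
        if len(self.shell_frequencies) != len(self.correlations):
            raise ValueError("one correlation per shell required")
        if np.any(np.diff(self.shell_frequencies) <= 0):
            raise ValueError("shell frequencies must increase strictly")


def _shell_index(shape, voxel_size: float):
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    grids = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(sum(g * g for g in grids))
    n = shape[0]
    # integer radius in Fourier-voxel units; shell width = 1/(n * voxel)
    return np.rint(f * n * voxel_size).astype(np.int64)


def compute_fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """FSC between two maps on shells one Fourier voxel wide.

    Per shell ``s``: ``Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 sum |F_b|^2)``,
    evaluated up to the Nyquist frequency.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share dimensions")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-9:
        raise ValueError("maps must share voxel size")
    n = map_a.box_size
    Fa = np.fft.fftn(map_a.data.astype(np.float64))
    Fb = np.fft.fftn(map_b.data.astype(np.float64))
    shell = _shell_index(map_a.shape, map_a.voxel_size)
    n_shells = n // 2 + 1
    flat = shell.ravel()
    keep = flat < n_shells
    flat = flat[keep]
    cross = np.bincount(flat, weights=(Fa * np.conj(Fb)).real.ravel()[keep],
                        minlength=n_shells)
    pa = np.bincount(flat, weights=(np.abs(Fa) ** 2).ravel()[keep],
                     minlength=n_shells)
    pb = np.bincount(flat, weights=(np.abs(Fb) ** 2).ravel()[keep],
                     minlength=n_shells)
    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros_like(cross),
                     where=denom > 0)
    corr = np.clip(corr, -1.0, 1.0)
    shell_width = 1.0 / (n * map_a.voxel_size)
    freqs = np.arange(1, n_shells) * shell_width
    return FSCCurve(freqs, corr[1:], shell_width)


@dataclass
class Resolution:
    resolution_A: float
    crossed: bool                  # False: curve never fell below threshold
    threshold: float


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> Resolution:
    """Resolution at the first crossing of the FSC below a threshold.

    Linear interpolation in (frequency, correlation) between the bracketing
    shells. A curve that never crosses reports the Nyquist resolution with
    ``crossed=False``.
    """
    f = curve.shell_frequencies
    c = curve.correlations
    if len(f) == 0:
        raise ValueError("empty FSC curve")
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return Resolution(1.0 / f[-1], False, threshold)
    i = below[0]
    if i == 0:
        return Resolution(1.0 / f[0], True, threshold)
    f_lo, f_hi = f[i - 1], f[i]
    c_lo, c_hi = c[i - 1], c[i]
    t = (c_lo - threshold) / (c_lo - c_hi)
    return Resolution(1.0 / (f_lo + t * (f_hi - f_lo)), True, threshold)


def split_series(series: TiltSeries, mode: str = "raw"
                 ) -> tuple[TiltSeries, TiltSeries]:
    """Even/odd split of a tilt series by tilt order.

    ``aligned`` carries the refined per-image shifts into both halves;
    ``raw`` zeroes them, the gold-standard protocol where each half is
    reconstructed independently so half-to-half noise stays uncorrelated.
    """
    if mode not in ("aligned", "raw"):
        raise ValueError("mode must be 'aligned' or 'raw'")
    if len(series) < 4:
        raise ValueError("need at least 4 images to split")
    halves = []
    for parity in (0, 1):
        idx = np.arange(parity, len(series), 2)
        shifts = series.shifts[idx] if mode == "aligned" \
            else np.zeros((len(idx), 2))
        true_shifts = None if series.true_shifts is None \
            else series.true_shifts[idx]
        halves.append(TiltSeries(series.images[idx], series.angles[idx],
                                 series.pixel_size, true_shifts=true_shifts,
                                 shifts=shifts, dose_note=series.dose_note))
    return halves[0], halves[1]


def register_halves(map_a: DensityMap, map_b: DensityMap) -> DensityMap:
    """Translate map B onto map A (whole-voxel cross-correlation peak).

    Two independently refined half-set reconstructions carry an arbitrary
    common-center offset; removing it before the FSC avoids penalising the
    correlation for a pure gauge difference. Only map B is moved.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share dimensions")
    A = map_a.data.astype(np.float64)
    B = map_b.data.astype(np.float64)
    cc = np.fft.ifftn(np.fft.fftn(A) * np.conj(np.fft.fftn(B))).real
    idx = np.unravel_index(np.argmax(cc), cc.shape)
    shift = [(i if i <= s // 2 else i - s) for i, s in zip(idx, cc.shape)]
    if all(s == 0 for s in shift):
        return map_b
    from scipy import ndimage as _ndi
    moved = _ndi.shift(map_b.data, shift, order=1, mode="constant", cval=0.0)
    return DensityMap(moved, map_b.voxel_size)


def gold_standard_fsc(map_a: DensityMap, map_b: DensityMap,
                      mask: SoftMask | None = None,
                      register: bool = True) -> FSCCurve:
    """FSC between two half-set maps with registration and solvent masking.

    When no mask is given, a particle-shaped soft mask (40 A low-pass,
    3x molecular mass, 6 px taper) is derived from the mean of the
    registered halves — the same mask construction the refinement uses —
    and applied to both maps to suppress solvent noise outside the
    particle.
    """
    if register:
        map_b = register_halves(map_a, map_b)
    if mask is None:
        from .masks import make_particle_mask
        mean_map = DensityMap((map_a.data + map_b.data) / 2.0,
                              map_a.voxel_size)
        mask = make_particle_mask(mean_map, taper=6.0)
    a = DensityMap(map_a.data * mask.weights, map_a.voxel_size)
    b = DensityMap(map_b.data * mask.weights, map_b.voxel_size)
    return compute_fsc(a, b)


def rasterize_model(coords: np.ndarray, box: int, voxel_size: float,
                    resolution_A: float,
                    weights: np.ndarray | None = None) -> DensityMap:
    """Gaussian-blob rasterization of atomic coordinates into a map.

    Atoms are splatted trilinearly and blurred so the resulting density is
    band-limited to ``resolution_A`` (half-amplitude), mirroring what map
    generators like pdb2mrc do at a stated resolution.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate set")
    half = (box - 1) / 2.0 * voxel_size
    if np.abs(coords).max() > half:
        raise ValueError("coordinates fall outside the map box")
    if weights is None:
        weights = np.ones(len(coords))
    vol = np.zeros((box, box, box), dtype=np.float64)
    c = (box - 1) / 2.0
    vox = np.empty_like(coords)
    vox[:, 0] = coords[:, 2] / voxel_size + c
    vox[:, 1] = coords[:, 1] / voxel_size + c
    vox[:, 2] = coords[:, 0] / voxel_size + c
    base = np.floor(vox).astype(np.int64)
    frac = vox - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (weights
                     * (frac[:, 0] if dz else 1 - frac[:, 0])
                     * (frac[:, 1] if dy else 1 - frac[:, 1])
                     * (frac[:, 2] if dx else 1 - frac[:, 2]))
                idx = np.clip(base + np.array([dz, dy, dx]), 0, box - 1)
                np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), w)
    blurred = lowpass(vol.astype(np.float32), resolution_A, voxel_size)
    return DensityMap(blurred, voxel_size)


def map_model_fsc(density: DensityMap, coords: np.ndarray,
                  resolution_for_rasterize: float = 20.0) -> FSCCurve:
    """FSC between a map and the rasterization of an atomic model."""
    model = rasterize_model(coords, density.box_size, density.voxel_size,
                            resolution_for_rasterize)
    return compute_fsc(density, model)


__all__ = [
    "SNRReport", "estimate_snr", "FSCCurve", "compute_fsc", "Resolution",
    "resolution_at_threshold", "split_series", "rasterize_model",
    "map_model_fsc", "register_halves", "gold_standard_fsc",
]
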