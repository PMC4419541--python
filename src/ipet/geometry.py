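"""Per-conformation domain geometry and ensemble flexibility statistics.

Each antibody conformation is summarised by nine vectors: three
center-to-center vectors between the domain mass centers, three domain
direction vectors (minimum principal inertia axis — the long axis of each
domain) and three plane-normal vectors (maximum principal inertia axis —
the normal of each domain's flattest plane). From these, six families of
measures are derived per particle: the three center distances, the
Fab1-Fc-Fab2 vertex angle at the Fc center, the Fab-Fab and Fab-Fc
direction angles, and the Fab-Fab and Fab-Fc plane-normal angles. Because
the two faces of a domain plane cannot be told apart at intermediate
resolution, normal angles are folded to at most 90 degrees.

Ensemble distributions are binned into histograms and fitted with
sixth-degree polynomials; the fitted peak location and the population
fraction of the peak's bin are the headline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FAB1, FAB2, FC, Conformation

#: Domain definitions as (chain, first residue, last residue) segments.
DEFAULT_DOMAIN_DEFINITION: dict[str, tuple[tuple[str, int, int], ...]] = {
    "Fab1": (("A", 1, 226), ("B", 1, 226)),
    "Fab2": (("C", 1, 226), ("D", 1, 226)),
    "Fc": (("B", 237, 444), ("D", 237, 444)),
    "linker1": (("B", 221, 236),),
    "linker2": (("D", 221, 236),),
}


def mass_center(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position (unit masses when none are given)."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate set")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _canonical_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip an axis vector so its first non-negligible component is positive."""
    for comp in v:
        if abs(comp) > tol:
            return v if comp > 0 else -v
    return v


def principal_axes(coords: np.ndarray, masses: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal inertia axes of a point cloud: (min, mid, max) by inertia.

    The inertia tensor is taken about the mass center; the minimum-inertia
    eigenvector runs along an elongated body, the maximum-inertia one is
    normal to a flattened body. Signs follow the first-nonzero-component-
    positive convention. Collinear (rank-deficient) clouds are rejected
    because their in-plane axes are undefined.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 points for principal axes")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    c = mass_center(coords, masses)
    r = coords - c
    if np.linalg.matrix_rank(r, tol=1e-8 * max(1.0, np.abs(r).max())) < 2:
        raise ValueError("degenerate (collinear) coordinates: principal "
                         "axes undefined")
    r2 = (masses[:, None] * r * r).sum()
    inertia = r2 * np.eye(3) - (masses[:, None] * r).T @ r
    evals, evecs = np.linalg.eigh(inertia)   # ascending eigenvalues
    axes = tuple(_canonical_sign(evecs[:, i]) for i in range(3))
    return axes


def conformation_from_atoms(coords: np.ndarray, chains: np.ndarray,
                            res_ids: np.ndarray,
                            domain_defs: dict | None = None,
                            source: str = "pdb") -> Conformation:
    """Measure a Conformation from labelled atomic coordinates.

    Domain membership follows the chain/residue-range definitions; each
    domain's direction and normal are its principal inertia axes. The
    direction vectors are oriented to point away from the Fc mass center
    (Fc's away from the Fab midpoint) so that direction angles are
    meaningful over the full 0-180 degree range.
    """
    defs = DEFAULT_DOMAIN_DEFINITION if domain_defs is None else domain_defs
    chains = np.asarray(chains)
    res_ids = np.asarray(res_ids)

    def domain_coords(name):
        sel = np.zeros(len(coords), dtype=bool)
        for chain, lo, hi in defs[name]:
            sel |= (chains == chain) & (res_ids >= lo) & (res_ids <= hi)
        if not sel.any():
            raise ValueError(f"no atoms found for domain {name}")
        return np.asarray(coords, float)[sel]

    centers = np.empty((3, 3))
    dirs = np.empty((3, 3))
    norms = np.empty((3, 3))
    pts = {}
    for idx, name in ((FAB1, "Fab1"), (FAB2, "Fab2"), (FC, "Fc")):
        pts[idx] = domain_coords(name)
        centers[idx] = mass_center(pts[idx])
    for idx in (FAB1, FAB2, FC):
        mn, _, mx = principal_axes(pts[idx])
        if idx == FC:
            outward = centers[FC] - 0.5 * (centers[FAB1] + centers[FAB2])
        else:
            outward = centers[idx] - centers[FC]
        if np.dot(mn, outward) < 0:
            mn = -mn
        norm = mx - np.dot(mx, mn) * mn    # enforce exact perpendicularity
        norms[idx] = norm / np.linalg.norm(norm)
        dirs[idx] = mn
    return Conformation(centers, dirs, norms, source=source)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def fold_to_90(angle_deg: float) -> float:
    """Fold an axis-pair angle into [0, 90] (plane sides indistinguishable)."""
    a = float(angle_deg) % 180.0
    return min(a, 180.0 - a)


@dataclass
class GeometryRecord:
    """The six measured quantities of one conformation (angstrom / degrees)."""

    dist_fab_fab: float
    dist_fab1_fc: float
    dist_fab2_fc: float
    vertex_angle: float          # Fab1-Fc-Fab2 at the Fc center
    dir_angle_fab_fab: float
    dir_angle_fab1_fc: float
    dir_angle_fab2_fc: float
    normal_angle_fab_fab: float  # folded to <= 90
    normal_angle_fab1_fc: float
    normal_angle_fab2_fc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def conformation_geometry(conf: Conformation) -> GeometryRecord:
    """Distances, vertex angle, direction angles and folded normal angles."""
    c = conf.centers
    v1 = c[FAB1] - c[FC]
    v2 = c[FAB2] - c[FC]
    d1, d2 = np.linalg.norm(v1), np.linalg.norm(v2)
    dff = np.linalg.norm(c[FAB1] - c[FAB2])
    if d1 < 1e-9 or d2 < 1e-9 or dff < 1e-9:
        raise ValueError("coincident domain centers: geometry undefined")
    d = conf.direction_vectors
    n = conf.normal_vectors
    return GeometryRecord(
        dist_fab_fab=float(dff),
        dist_fab1_fc=float(d1),
        dist_fab2_fc=float(d2),
        vertex_angle=angle_between(v1, v2),
        dir_angle_fab_fab=angle_between(d[FAB1], d[FAB2]),
        dir_angle_fab1_fc=angle_between(d[FAB1], d[FC]),
        dir_angle_fab2_fc=angle_between(d[FAB2], d[FC]),
        normal_angle_fab_fab=fold_to_90(angle_between(n[FAB1], n[FAB2])),
        normal_angle_fab1_fc=fold_to_90(angle_between(n[FAB1], n[FC])),
        normal_angle_fab2_fc=fold_to_90(angle_between(n[FAB2], n[FC])),
    )


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto reference.

    SVD-based, reflection-free (proper rotation). Returns (R, t) such that
    ``mobile @ R.T + t`` superposes onto reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must match in shape")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def superpose_on_fc(structures: list, domain_defs: dict | None = None):
    """Align an ensemble on its Fc domains (first structure is the frame).

    Each structure is a ``(coords, chains, res_ids)`` triple. All atoms of
    each structure are moved by the rigid transform that superposes its Fc
    atoms onto the first structure's Fc. Returns the aligned coordinate
    arrays, the (R, t) transforms and the per-structure Fc RMSD after
    alignment. Structures must have identical Fc atom counts.
    """
    defs = DEFAULT_DOMAIN_DEFINITION if domain_defs is None else domain_defs

    def fc_atoms(coords, chains, res_ids):
        chains = np.asarray(chains)
        res_ids = np.asarray(res_ids)
        sel = np.zeros(len(coords), dtype=bool)
        for chain, lo, hi in defs["Fc"]:
            sel |= (chains == chain) & (res_ids >= lo) & (res_ids <= hi)
        if not sel.any():
            missing = ", ".join(f"{c}:{lo}-{hi}" for c, lo, hi in defs["Fc"])
            raise ValueError(f"structure is missing Fc residues ({missing})")
        return np.asarray(coords, float)[sel]

    ref = fc_atoms(*structures[0])
    aligned, transforms, rmsds = [], [], []
    for coords, chains, res_ids in structures:
        fc = fc_atoms(coords, chains, res_ids)
        if fc.shape != ref.shape:
            raise ValueError("Fc atom counts differ between structures")
        R, t = kabsch(fc, ref)
        moved = np.asarray(coords, float) @ R.T + t
        fc_moved = fc @ R.T + t
        rmsds.append(float(np.sqrt(((fc_moved - ref) ** 2).sum(axis=1).mean())))
        aligned.append(moved)
        transforms.append((R, t))
    return aligned, transforms, rmsds


@dataclass
class HistogramFit:
    """A binned distribution with a sixth-degree polynomial fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    coefficients: np.ndarray        # polynomial, highest degree first
    peak_location: float            # argmax of the fit on the data range
    peak_population: float          # fraction of samples in the peak's bin
    n: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_histogram_and_fit(values, bin_width: float,
                            fit_degree: int = 6) -> HistogramFit:
    """Histogram on uniform bins plus a polynomial least-squares fit.

    The fit is to raw counts at bin centers; the peak is the argmax of the
    fitted polynomial over the data range and the peak population is the
    fraction of samples falling in the bin containing it. Degenerate
    single-bin samples short-circuit to that bin with population 1.
    """
    values = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if values.size == 0:
        raise ValueError("no values to histogram")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(centers) == 1:
        return HistogramFit(edges, counts, np.array([counts[0]]),
                            float(centers[0]), 1.0, values.size)
    if len(centers) < fit_degree + 2:
        raise ValueError(
            f"need at least {fit_degree + 2} bins for a degree-{fit_degree} "
            f"fit, got {len(centers)}; widen the data or shrink bin_width")
    coeffs = np.polyfit(centers, counts, fit_degree)
    dense = np.linspace(values.min(), values.max(), 2048)
    fit_vals = np.polyval(coeffs, dense)
    peak_loc = float(dense[np.argmax(fit_vals)])
    peak_bin = np.clip(np.searchsorted(edges, peak_loc, side="right") - 1,
                       0, len(counts) - 1)
    return HistogramFit(edges, counts, coeffs, peak_loc,
                        float(counts[peak_bin] / values.size), values.size)


#: Histogram bin widths at the reporting precision of the six measures.
DEFAULT_BIN_WIDTHS = {
    "dist_fab_fab": 5.0, "dist_fab_fc": 5.0,
    "vertex_angle": 8.0,
    "dir_angle_fab_fab": 10.0, "dir_angle_fab_fc": 10.0,
    "normal_angle_fab_fab": 10.0, "normal_angle_fab_fc": 10.0,
}


def ensemble_report(records: list[GeometryRecord],
                    bin_widths: dict | None = None,
                    windows: dict | None = None):
    """Histograms + summary table for the six measures over an ensemble.

    Fab1/Fc and Fab2/Fc measures are pooled (the two Fabs are
    interchangeable), giving seven histograms across the six measure
    families. ``windows`` may map a measure name to an (lo, hi) interval;
    the fraction of samples inside is added to the summary (e.g. the
    fraction of vertex angles within 40-72 degrees).
    """
    if len(records) < 2:
        raise ValueError("ensemble statistics need at least 2 records")
    bw = dict(DEFAULT_BIN_WIDTHS)
    if bin_widths:
        bw.update(bin_widths)
    series = {
        "dist_fab_fab": [r.dist_fab_fab for r in records],
        "dist_fab_fc": [x for r in records
                        for x in (r.dist_fab1_fc, r.dist_fab2_fc)],
        "vertex_angle": [r.vertex_angle for r in records],
        "dir_angle_fab_fab": [r.dir_angle_fab_fab for r in records],
        "dir_angle_fab_fc": [x for r in records
                             for x in (r.dir_angle_fab1_fc,
                                       r.dir_angle_fab2_fc)],
        "normal_angle_fab_fab": [r.normal_angle_fab_fab for r in records],
        "normal_angle_fab_fc": [x for r in records
                                for x in (r.normal_angle_fab1_fc,
                                          r.normal_angle_fab2_fc)],
    }
    fits = {}
    rows = []
    for name, vals in series.items():
        vals = np.asarray(vals, dtype=float)
        # narrow distributions get a lower polynomial degree rather than
        # no fit at all; the default sixth degree needs eight bins
        fit = None
        for degree in (6, 4, 2):
            try:
                fit = build_histogram_and_fit(vals, bw[name],
                                              fit_degree=degree)
                break
            except ValueError:
                continue
        fits[name] = fit
        row = {
            "measure": name, "n": len(vals),
            "min": vals.min(), "max": vals.max(),
            "peak": fit.peak_location if fit else np.nan,
            "peak_halfbin": bw[name] / 2,
            "peak_population_pct": 100 * fit.peak_population if fit else np.nan,
        }
        if windows and name in windows:
            lo, hi = windows[name]
            row["window_lo"], row["window_hi"] = lo, hi
            row["window_fraction_pct"] = 100 * np.mean((vals >= lo)
                                                       & (vals <= hi))
        rows.append(row)
    return fits, pd.DataFrame(rows)


__all__ = [
    "DEFAULT_DOMAIN_DEFINITION", "DEFAULT_BIN_WIDTHS", "mass_center",
    "principal_axes", "conformation_from_atoms", "angle_between",
    "fold_to_90", "GeometryRecord", "conformation_geometry", "kabsch",
    "superpose_on_fc", "HistogramFit", "build_histogram_and_fit",
    "ensemble_report",
]
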