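"""File I/O: MRC volumes and stacks, tilt-angle lists, PDB pseudo-atoms.

MRC/CCP4 reading and writing is delegated to gemmi. Tilt stacks are stored
as an MRC volume whose sections (first axis) are the tilt images, with the
angles in a sibling plain-text ``.tlt`` file, one angle in degrees per
line in section order — the layout tomography packages exchange.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .core import Conformation, DensityMap, TiltSeries


def write_mrc(path, data: np.ndarray, voxel_size: float) -> None:
    """Write a 2-D image, 3-D volume or image stack as an MRC map."""
    data = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if data.ndim == 2:
        data = data[None]
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    nz, ny, nx = data.shape
    m.grid.unit_cell = gemmi.UnitCell(nx * voxel_size, ny * voxel_size,
                                      nz * voxel_size, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns (array, voxel size in angstroms)."""
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / data.shape[-1]
    return data, float(voxel)


def write_map(path, density: DensityMap) -> None:
    write_mrc(path, density.data, density.voxel_size)


def read_map(path) -> DensityMap:
    data, voxel = read_mrc(path)
    return DensityMap(data, voxel)


def write_tilt_series(stack_path, tlt_path, series: TiltSeries) -> None:
    """Write the image stack (MRC) plus the ``.tlt`` angle file."""
    write_mrc(stack_path, series.images, series.pixel_size)
    Path(tlt_path).write_text(
        "".join(f"{a:.2f}\n" for a in series.angles))


def read_tilt_series(stack_path, tlt_path) -> TiltSeries:
    images, voxel = read_mrc(stack_path)
    angles = np.array([float(line) for line in
                       Path(tlt_path).read_text().split()])
    return TiltSeries(images, angles, voxel)


def write_pseudo_atoms(path, coords: np.ndarray, chains: np.ndarray,
                       res_ids: np.ndarray) -> None:
    """Write pseudo-atoms as a PDB of CA dummies with chain/residue labels."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.asarray(chains, dtype="U4")
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.res_name = np.full(n, "GLY", dtype="U3")
    atoms.atom_name = np.full(n, "CA", dtype="U4")
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.hetero = np.full(n, False)
    f = PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_pseudo_atoms(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a PDB; returns (coords, chain ids, residue ids)."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1)
    return (np.asarray(atoms.coord, dtype=float),
            np.asarray(atoms.chain_id), np.asarray(atoms.res_id, dtype=int))


def write_shifts_csv(path, angles: np.ndarray, shifts: np.ndarray,
                     true_shifts: np.ndarray | None = None) -> None:
    cols = {"angle_deg": angles,
            "shift_dx_px": shifts[:, 0], "shift_dy_px": shifts[:, 1]}
    if true_shifts is not None:
        cols["true_dx_px"] = true_shifts[:, 0]
        cols["true_dy_px"] = true_shifts[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_fsc_csv(path, curve) -> None:
    """FSC curve as two columns: resolution in angstroms, correlation."""
    pd.DataFrame({
        "resolution_A": 1.0 / curve.shell_frequencies,
        "correlation": curve.correlations,
    }).to_csv(path, index=False)


def write_conformation_json(path, conf: Conformation) -> None:
    import json
    payload = {
        "centers_A": conf.centers.tolist(),
        "direction_vectors": conf.direction_vectors.tolist(),
        "normal_vectors": conf.normal_vectors.tolist(),
        "source": conf.source,
    }
    if conf.rotations is not None:
        payload["rotations"] = conf.rotations.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_conformation_json(path) -> Conformation:
    import json
    d = json.loads(Path(path).read_text())
    return Conformation(np.array(d["centers_A"]),
                        np.array(d["direction_vectors"]),
                        np.array(d["normal_vectors"]),
                        rotations=(np.array(d["rotations"])
                                   if "rotations" in d else None),
                        source=d.get("source", "fitted"))


__all__ = [
    "write_mrc", "read_mrc", "write_map", "read_map", "write_tilt_series",
    "read_tilt_series", "write_pseudo_atoms", "read_pseudo_atoms",
    "write_shifts_csv", "write_fsc_csv", "write_conformation_json",
    "read_conformation_json",
]
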