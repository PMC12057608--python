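"""Spatial distribution functions (SDF) in a body-fixed molecular frame.

The SDF is the 3D density of a target species around a reference molecule,
expressed in the reference molecule's own (body-fixed) coordinate frame and
normalized so that the far-field value is the bulk density (relative density
1).  An isosurface at e.g. 0.5 then marks regions holding half the bulk
density of the target.

Body frame definition: for references with >= 3 non-collinear reference
particles, each frame's reference geometry is superposed onto the first
frame's geometry by the Kabsch algorithm (proper rotation only), and target
coordinates are expressed in that frame.  For two-particle references (a bead
plus a single satellite, as produced by the synthetic generator) an
orthonormal frame is completed with a deterministic lab-vector
orthogonalization; such a frame fixes only the bead-satellite axis, which is
sufficient for axially symmetric statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from enantiodyn.core_io import ANGSTROM_PER_NM, SpeciesMap, Trajectory

__all__ = ["Grid3D", "compute_sdf", "write_cube", "read_cube"]

BOHR_PER_ANGSTROM = 1.8897259886


@dataclass
class Grid3D:
    """Regular cubic grid of (relative) density values.

    ``origin`` (A) is the corner of the first voxel, ``spacing`` (A) the voxel
    edge, ``values`` the 3D array (dimensionless relative density in
    "relative" mode, mean counts per frame per voxel in "counts" mode)."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    mode: str = "relative"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


def _kabsch(current: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||R @ current_i - template_i|| for
    centered point sets (n, 3)."""
    h = current.T @ template
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def _two_point_frame(axis: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows) whose first axis is ``axis``;
    completed with a deterministic lab vector."""
    e1 = axis / np.linalg.norm(axis)
    lab = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = lab - np.dot(lab, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3])


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def compute_sdf(
    traj: Trajectory,
    species_map: SpeciesMap,
    reference_selector: dict,
    target_selector: dict,
    extent: float = 20.0,
    spacing: float = 0.5,
    mode: str = "relative",
) -> Grid3D:
    """Accumulate the SDF of target particles around the selected reference
    molecules.

    ``reference_selector`` / ``target_selector`` are dicts with optional keys
    "species" and "chirality".  The grid spans ``extent`` Angstrom per axis,
    centred on the reference centroid.  ``mode``: "relative" normalizes by
    frame count, voxel volume and bulk target density (far field -> 1);
    "counts" reports mean target counts per frame per voxel.
    """
    if mode not in ("relative", "counts"):
        raise ValueError("mode must be 'relative' or 'counts'")
    ref_ids = species_map.molecule_ids(
        species=reference_selector.get("species"), chirality=reference_selector.get("chirality")
    )
    tgt_ids = species_map.molecule_ids(
        species=target_selector.get("species"), chirality=target_selector.get("chirality")
    )
    if len(ref_ids) == 0:
        raise ValueError("reference selector matches no molecules")
    if len(tgt_ids) == 0:
        raise ValueError("target selector matches no molecules")
    tgt_parts = np.concatenate([species_map.particles_of(int(m)) for m in tgt_ids])

    box = traj.box
    n_bins = int(round(extent / spacing))
    origin = np.full(3, -extent / 2.0)
    hist = np.zeros((n_bins, n_bins, n_bins))
    half = extent / 2.0

    n_deposits_frames = 0
    for ref_id in ref_ids:
        parts = species_map.particles_of(int(ref_id))
        # assemble the molecule min-image-local to its first particle
        rel0 = _minimum_image(
            traj.frames[0, parts, :] - traj.frames[0, parts[0], :][None, :], box
        )
        template = rel0 - rel0.mean(axis=0)
        multi_point = len(parts) >= 3
        if multi_point and np.linalg.matrix_rank(template, tol=1e-8) < 2:
            raise ValueError(f"reference particles of molecule {ref_id} are collinear")
        own = set(int(p) for p in parts)
        tgt = np.array([p for p in tgt_parts if int(p) not in own])
        if len(tgt) == 0:
            raise ValueError("target selection empty after removing reference particles")

        for f in range(traj.n_frames):
            rel = _minimum_image(
                traj.frames[f, parts, :] - traj.frames[f, parts[0], :][None, :], box
            )
            centroid = traj.frames[f, parts[0], :] + rel.mean(axis=0)
            current = rel - rel.mean(axis=0)
            if multi_point:
                rot = _kabsch(current, template)
            else:
                rot = _two_point_frame(current[1] - current[0])
            disp = _minimum_image(traj.frames[f, tgt, :] - centroid[None, :], box)
            body = disp @ rot.T * ANGSTROM_PER_NM
            inside = np.all(np.abs(body) < half, axis=1)
            if inside.any():
                idx = np.floor((body[inside] - origin[None, :]) / spacing).astype(int)
                np.add.at(hist, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
            n_deposits_frames += 1

    mean_counts = hist / n_deposits_frames
    if mode == "counts":
        return Grid3D(origin=origin, spacing=spacing, values=mean_counts, mode=mode)
    bulk_density = len(tgt) / np.prod(box * ANGSTROM_PER_NM)  # particles / A^3
    values = mean_counts / (spacing**3) / bulk_density
    return Grid3D(origin=origin, spacing=spacing, values=values, mode=mode)


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------


def write_cube(
    grid: Grid3D,
    path: str | Path,
    reference_structure: np.ndarray | None = None,
    comment: str = "enantiodyn spatial distribution function",
) -> Path:
    """Write the grid as a Gaussian cube file (lengths in Bohr, positive voxel
    counts).  ``reference_structure`` is an optional (n, 3) array of atom
    positions in Angstrom embedded for isosurface viewing (written as carbon
    atoms); without it a single dummy atom at the origin is written."""
    path = Path(path)
    atoms = (
        np.asarray(reference_structure, dtype=float)
        if reference_structure is not None
        else np.zeros((1, 3))
    )
    b = BOHR_PER_ANGSTROM
    nx, ny, nz = grid.values.shape
    with open(path, "w") as f:
        f.write(comment + "\n")
        f.write(f"mode={grid.mode}\n")
        ox, oy, oz = grid.origin * b
        f.write(f"{len(atoms):5d} {ox:13.6f} {oy:13.6f} {oz:13.6f}\n")
        f.write(f"{nx:5d} {grid.spacing * b:13.6f} {0.0:13.6f} {0.0:13.6f}\n")
        f.write(f"{ny:5d} {0.0:13.6f} {grid.spacing * b:13.6f} {0.0:13.6f}\n")
        f.write(f"{nz:5d} {0.0:13.6f} {0.0:13.6f} {grid.spacing * b:13.6f}\n")
        for pos in atoms:
            x, y, z = pos * b
            f.write(f"{6:5d} {6.0:13.6f} {x:13.6f} {y:13.6f} {z:13.6f}\n")
        flat = grid.values.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                f.write(" ".join(f"{v:14.7e}" for v in row[start : start + 6]) + "\n")
    return path


def read_cube(path: str | Path) -> tuple[Grid3D, np.ndarray]:
    """Read a Gaussian cube file written by :func:`write_cube`; returns the
    grid (Angstrom) and the embedded atom positions (Angstrom)."""
    path = Path(path)
    with open(path) as f:
        f.readline()
        mode_line = f.readline().strip()
        mode = mode_line.split("=", 1)[1] if "=" in mode_line else "relative"
        parts = f.readline().split()
        n_atoms = int(parts[0])
        origin = np.array(parts[1:4], dtype=float)
        axes = []
        shape = []
        for _ in range(3):
            parts = f.readline().split()
            shape.append(int(parts[0]))
            axes.append(np.array(parts[1:4], dtype=float))
        atoms = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            parts = f.readline().split()
            atoms[i] = np.array(parts[2:5], dtype=float)
        values = np.fromstring(f.read(), sep=" ").reshape(shape)
    spacing = axes[0][0] / BOHR_PER_ANGSTROM
    grid = Grid3D(
        origin=origin / BOHR_PER_ANGSTROM,
        spacing=float(spacing),
        values=values,
        mode=mode,
    )
    return grid, atoms / BOHR_PER_ANGSTROM
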