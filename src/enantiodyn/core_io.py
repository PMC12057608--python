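"""Domain types, unit conventions, and trajectory/table I/O.

Unit conventions
----------------
* trajectory coordinates: nm; times: ps (GRO convention)
* distances in complexation/SDF reports: Angstrom
* diffusion coefficients: 1e-10 m^2/s (the scale DOSY tables are printed in)
* free energies: kcal/mol; chemical shifts: ppm
* gradient schedules: SI (T/m, s, rad s^-1 T^-1)

Supported trajectory formats: multi-frame XYZ and PDB, single-frame GRO
(structure + box), and a single-file HDF5 container (``.h5``) holding chunked
coordinate arrays plus a metadata block (times, box, wrapped flag, species-map
digest).  All external formats are read and written through MDAnalysis; the
container through h5py.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ANGSTROM_PER_NM",
    "NM_PER_ANGSTROM",
    "Trajectory",
    "SpeciesMap",
    "GradientSchedule",
    "AttenuationSeries",
    "ConformerRecord",
    "read_trajectory",
    "write_trajectory",
    "read_species_map",
    "write_species_map",
]

ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1

#: conversion from an MSD slope in nm^2/ns to a diffusion coefficient unit of
#: 1e-10 m^2/s (1 nm^2/ns = 1e-9 m^2/s = 10 x 1e-10 m^2/s)
NM2_PER_NS_TO_1E10_M2_S = 10.0

VALID_CHIRALITY = {"R", "S", "none"}
VALID_ROLES = {"chiral_H", "heavy", "other"}


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed into a valid Trajectory."""


@dataclass
class Trajectory:
    """A trajectory of point particles in an orthorhombic periodic box.

    Attributes
    ----------
    times : ndarray, shape (n_frames,)
        Frame times in ps; strictly increasing, uniformly spaced.
    frames : ndarray, shape (n_frames, n_particles, 3)
        Coordinates in nm.
    box : ndarray, shape (3,)
        Orthorhombic box edge lengths in nm.
    wrapped : bool
        Whether coordinates are wrapped into the primary box image.
        Unwrapping is always an explicit operation (see
        :func:`enantiodyn.diffusion.unwrap`), never implicit.
    """

    times: np.ndarray
    frames: np.ndarray
    box: np.ndarray
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n_frames, n_particles, 3), got {self.frames.shape}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length must equal number of frames")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be 3 positive edge lengths (nm)")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
                raise ValueError("times must be uniformly spaced (rtol 1e-9)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    @property
    def dt_ps(self) -> float:
        """Frame spacing in ps (0 for single-frame trajectories)."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def duration_ns(self) -> float:
        """Total time span (last minus first frame time) in ns."""
        return float(self.times[-1] - self.times[0]) / 1000.0


@dataclass
class SpeciesMap:
    """Per-particle molecular annotation.

    Backed by a DataFrame with columns ``particle`` (0-based index into the
    trajectory's particle axis), ``molecule_id``, ``species`` (e.g. MA, CRA,
    SOLVENT), ``chirality`` (R | S | none) and ``role``
    (chiral_H | heavy | other).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["particle", "molecule_id", "species", "chirality", "role"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"species map missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("species map has no particles")
        t = self.table
        if t["particle"].duplicated().any():
            dup = t.loc[t["particle"].duplicated(), "particle"].iloc[0]
            raise ValueError(f"duplicate particle index {dup}")
        bad_chir = set(t["chirality"]) - VALID_CHIRALITY
        if bad_chir:
            raise ValueError(f"unknown chirality labels: {sorted(bad_chir)}")
        bad_role = set(t["role"]) - VALID_ROLES
        if bad_role:
            raise ValueError(f"unknown role labels: {sorted(bad_role)}")
        # every MA molecule carries exactly one chiral_H reporter
        ma = t[t["species"] == "MA"]
        if len(ma):
            n_h = ma.groupby("molecule_id")["role"].apply(lambda r: (r == "chiral_H").sum())
            bad = n_h[n_h != 1]
            if len(bad):
                raise ValueError(
                    f"MA molecules must have exactly one chiral_H particle; "
                    f"violated by molecule_id(s) {list(bad.index)}"
                )

    @property
    def n_particles(self) -> int:
        return len(self.table)

    def molecule_ids(self, species: str | None = None, chirality: str | None = None) -> np.ndarray:
        """Sorted unique molecule ids, optionally filtered by species/chirality."""
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if chirality is not None:
            t = t[t["chirality"] == chirality]
        return np.sort(t["molecule_id"].unique())

    def particles_of(self, molecule_id: int) -> np.ndarray:
        """Particle indices belonging to one molecule."""
        t = self.table
        return t.loc[t["molecule_id"] == molecule_id, "particle"].to_numpy()

    def chiral_h_particle(self, molecule_id: int) -> int:
        """Index of the chiral-centre hydrogen particle of an MA molecule."""
        t = self.table
        sel = t[(t["molecule_id"] == molecule_id) & (t["role"] == "chiral_H")]
        if len(sel) != 1:
            raise ValueError(f"molecule {molecule_id} has no unique chiral_H particle")
        return int(sel["particle"].iloc[0])

    def chirality_of(self, molecule_id: int) -> str:
        t = self.table
        vals = t.loc[t["molecule_id"] == molecule_id, "chirality"].unique()
        return str(vals[0])

    def species_of(self, molecule_id: int) -> str:
        t = self.table
        vals = t.loc[t["molecule_id"] == molecule_id, "species"].unique()
        return str(vals[0])

    def swap_chirality(self) -> "SpeciesMap":
        """Return a copy with all R and S labels exchanged (mirror system)."""
        t = self.table.copy()
        t["chirality"] = t["chirality"].map({"R": "S", "S": "R", "none": "none"})
        return SpeciesMap(t)

    def digest(self) -> str:
        """Stable content hash, embedded in container files for provenance."""
        payload = self.table.sort_values("particle").to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class GradientSchedule:
    """Pulsed-field-gradient schedule of a (Oneshot-style) diffusion experiment.

    Parameters are in SI units: ``gamma`` gyromagnetic ratio (rad s^-1 T^-1),
    ``little_delta`` gradient pulse duration delta (s), ``big_delta`` diffusion
    time Delta (s), ``g_values`` gradient strengths (T/m), ``alpha``
    dimensionless unbalancing factor of the Oneshot sequence (0 recovers the
    classical Stejskal-Tanner decay constant), ``tau`` gradient-pair spacing (s).
    """

    gamma: float
    little_delta: float
    big_delta: float
    g_values: np.ndarray
    alpha: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        self.g_values = np.asarray(self.g_values, dtype=float)
        if np.any(self.g_values < 0):
            raise ValueError("gradient strengths must be non-negative")
        if np.any(np.diff(self.g_values) < 0):
            raise ValueError("gradient strengths must be non-decreasing")
        if not self.little_delta < self.big_delta:
            raise ValueError("gradient pulse duration delta must be < diffusion time Delta")


PROTON_GAMMA = 2.675221e8  # rad s^-1 T^-1


def oneshot_schedule(
    n_increments: int = 16,
    g_max_fraction: float = 0.80,
    g_min_fraction: float = 0.10,
    max_gradient: float = 0.535,
    little_delta: float = 1.5e-3,
    big_delta: float = 60e-3,
    alpha: float = 0.0,
    tau: float = 0.0,
    gamma: float = PROTON_GAMMA,
) -> GradientSchedule:
    """A typical 1H DOSY schedule: gradient strength ramped quadratically from
    ``g_min_fraction`` to ``g_max_fraction`` of the probe's maximum nominal
    gradient (default 53.5 G/cm = 0.535 T/m), 16 increments.  The default
    delta/Delta give roughly 80-85% attenuation between first and last
    increment for a small molecule in chloroform (D ~ 1e-9 m^2/s).
    """
    u = np.linspace(0.0, 1.0, n_increments)
    fractions = g_min_fraction + (g_max_fraction - g_min_fraction) * u**2
    return GradientSchedule(
        gamma=gamma,
        little_delta=little_delta,
        big_delta=big_delta,
        g_values=fractions * max_gradient,
        alpha=alpha,
        tau=tau,
    )


@dataclass
class AttenuationSeries:
    """Measured (or synthetic) peak intensity versus gradient strength."""

    peak_label: str
    intensities: np.ndarray
    schedule: GradientSchedule

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.schedule.g_values.shape:
            raise ValueError("intensities and gradient values must align")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive")
        # the lowest-gradient point must carry (close to) the maximum signal;
        # a 5% headroom tolerates measurement noise on nearly equal increments
        if self.intensities[0] < self.intensities.max() * 0.95:
            raise ValueError("first (lowest-gradient) intensity must be the maximum")


@dataclass
class ConformerRecord:
    """One conformer of a labelled complex class.

    ``complex_class`` combines the pairing and the resolving-agent chirality,
    e.g. ``('heterochiral', 'R')``; ``G`` is the conformer free energy in
    kcal/mol and ``shift_chiral_H`` the isotropic chemical shift (ppm) of the
    chiral-centre hydrogen.  ``weight`` is filled in by Boltzmann weighting.
    """

    complex_class: str
    G: float
    shift_chiral_H: float
    weight: float | None = None


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

_MDA_FORMATS = {".xyz": "XYZ", ".pdb": "PDB", ".gro": "GRO"}


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "container"
    if suffix in _MDA_FORMATS:
        return suffix.lstrip(".")
    raise TrajectoryParseError(f"cannot infer trajectory format from {path.name}")


def read_trajectory(
    path: str | Path,
    format_hint: str | None = None,
    dt_ps: float = 1.0,
    box_nm: tuple[float, float, float] | None = None,
    wrapped: bool = True,
) -> Trajectory:
    """Read a trajectory file, converting coordinates to nm and times to ps.

    Parameters
    ----------
    path : path to an XYZ, PDB, GRO, or internal ``.h5`` container file.
    format_hint : override the extension-based format detection
        ("xyz", "pdb", "gro", "container").
    dt_ps : frame spacing used when the format carries no time axis (XYZ, PDB).
    box_nm : box edges for formats that carry none (XYZ); required there.
    wrapped : whether coordinates should be flagged as periodic-wrapped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "container":
        return _read_container(path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=_MDA_FORMATS["." + fmt])
        except FileNotFoundError:
            raise
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise TrajectoryParseError(f"failed to parse {path.name}: {exc}") from exc

        n_particles = len(u.atoms)
        frames = []
        boxes = []
        for i, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != n_particles:
                raise TrajectoryParseError(
                    f"inconsistent particle count at frame {i}: "
                    f"{ts.positions.shape[0]} != {n_particles}"
                )
            frames.append(ts.positions.copy() * NM_PER_ANGSTROM)
            boxes.append(None if ts.dimensions is None else ts.dimensions[:3].copy())

    frames_arr = np.asarray(frames)
    n_frames = frames_arr.shape[0]
    times = np.arange(n_frames, dtype=float) * dt_ps

    if box_nm is not None:
        box = np.asarray(box_nm, dtype=float)
    elif boxes[0] is not None and np.all(boxes[0] > 0):
        box = np.asarray(boxes[0], dtype=float) * NM_PER_ANGSTROM
    else:
        raise TrajectoryParseError(
            f"{path.name} carries no box information; pass box_nm explicitly"
        )
    return Trajectory(times=times, frames=frames_arr, box=box, wrapped=wrapped)


def write_trajectory(traj: Trajectory, path: str | Path, format_hint: str | None = None) -> Path:
    """Write a trajectory; format from extension or ``format_hint``.

    XYZ is written at 9 decimals (round-trips to < 1e-6 nm); PDB at the
    format's fixed 3 decimals in Angstrom (1e-4 nm); GRO writes the first
    frame only (structure file).  The ``.h5`` container is lossless.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "container":
        _write_container(traj, path)
        return path

    import MDAnalysis as mda

    n = traj.n_particles
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", ["X"] * n)
    u.dimensions = [*(traj.box * ANGSTROM_PER_NM), 90.0, 90.0, 90.0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "gro":
            u.atoms.positions = traj.frames[0] * ANGSTROM_PER_NM
            u.atoms.write(str(path))
        else:
            writer_kwargs = {"precision": 9} if fmt == "xyz" else {}
            with mda.Writer(str(path), n_atoms=n, **writer_kwargs) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame * ANGSTROM_PER_NM
                    w.write(u.atoms)
    return path


def _write_container(traj: Trajectory, path: Path, species_digest: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        chunk = (min(64, traj.n_frames), traj.n_particles, 3)
        f.create_dataset("frames", data=traj.frames, chunks=chunk)
        f.create_dataset("times", data=traj.times)
        f.create_dataset("box", data=traj.box)
        f.attrs["wrapped"] = traj.wrapped
        f.attrs["coordinate_unit"] = "nm"
        f.attrs["time_unit"] = "ps"
        if species_digest is not None:
            f.attrs["species_digest"] = species_digest


def _read_container(path: Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            times=f["times"][()],
            frames=f["frames"][()],
            box=f["box"][()],
            wrapped=bool(f.attrs.get("wrapped", True)),
        )


# ---------------------------------------------------------------------------
# species map and tabular I/O
# ---------------------------------------------------------------------------


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a species map from delimited text with header
    (particle, molecule_id, species, chirality, role)."""
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python")
    if len(table) == 0:
        raise ValueError(f"{path.name}: no particles")
    return SpeciesMap(table)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> Path:
    path = Path(path)
    species_map.table.to_csv(path, index=False)
    return path


def read_attenuation_table(
    path: str | Path, schedule: GradientSchedule
) -> list[AttenuationSeries]:
    """Read a delimited table (peak_label, g, intensity) into one
    AttenuationSeries per peak; rows must be ordered by increasing g."""
    table = pd.read_csv(Path(path), sep=None, engine="python")
    out = []
    for label, grp in table.groupby("peak_label", sort=False):
        g = grp["g"].to_numpy(dtype=float)
        if not np.allclose(g, schedule.g_values, rtol=1e-9):
            raise ValueError(f"peak {label}: gradient values do not match schedule")
        out.append(
            AttenuationSeries(
                peak_label=str(label),
                intensities=grp["intensity"].to_numpy(dtype=float),
                schedule=schedule,
            )
        )
    return out


def read_conformer_table(path: str | Path) -> list[ConformerRecord]:
    """Read a conformer table (complex_class, conformer_id, G_kcalmol, shift_ppm)."""
    table = pd.read_csv(Path(path), sep=None, engine="python")
    return [
        ConformerRecord(
            complex_class=str(row["complex_class"]),
            G=float(row["G_kcalmol"]),
            shift_chiral_H=float(row["shift_ppm"]),
        )
        for _, row in table.iterrows()
    ]
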