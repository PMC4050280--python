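"""Shared data types and file I/O.

Conventions used throughout the package
---------------------------------------
* Positions are in Å. Voxel indices are 0-based; the centre of voxel
  ``(i, j, k)`` sits at ``origin + (index + 0.5) * voxel_size``.
* Orientations are intrinsic Z-Y-Z Euler triplets ``(phi, theta, psi)`` in
  degrees. The rotation takes the template (reference) frame into the
  tomogram frame: ``R = Rz(phi) @ Ry(theta) @ Rz(psi)``.
* Density is *dark*: protein and membrane are negative, background is zero,
  matching the local-minima picking rule.
* Maps are MRC2014 mode 2 (float32); pixel size is carried in the cell
  dimensions and the origin in header words 50-52.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


class MapFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted."""


class SchemaError(ValueError):
    """Raised when a particle table violates the documented column set."""


# --------------------------------------------------------------------------- #
# Euler angle helpers
# --------------------------------------------------------------------------- #

def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for intrinsic Z-Y-Z Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`, angles in canonical ranges."""
    import warnings

    with warnings.catch_warnings():
        # gimbal lock is resolved deterministically by normalize_euler
        warnings.simplefilter("ignore", UserWarning)
        phi, theta, psi = Rotation.from_matrix(matrix).as_euler(
            "ZYZ", degrees=True)
    return normalize_euler(phi, theta, psi)


def normalize_euler(phi: float, theta: float, psi: float) -> tuple[float, float, float]:
    """Canonicalize a Z-Y-Z triplet: phi, psi in [0, 360), theta in [0, 180].

    Triplets describing the same rotation map to the same canonical triplet,
    so the operation is idempotent.
    """
    import warnings

    r = Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True)
    with warnings.catch_warnings():
        # gimbal lock at theta ~ 0/180 is resolved explicitly below
        warnings.simplefilter("ignore", UserWarning)
        p, t, s = r.as_euler("ZYZ", degrees=True)
    # as_euler returns theta in [0, 180], phi/psi in (-180, 180]
    p = p % 360.0
    s = s % 360.0
    # resolve the gimbal ambiguity at theta ~ 0/180 deterministically:
    # fold the free angle into psi.
    if t < 1e-9 or abs(t - 180.0) < 1e-9:
        s = (p + s) % 360.0 if t < 1e-9 else (s - p) % 360.0
        p = 0.0
    if p >= 360.0 - 1e-9:
        p = 0.0
    if s >= 360.0 - 1e-9:
        s = 0.0
    return float(p), float(t), float(s)


# --------------------------------------------------------------------------- #
# Density maps
# --------------------------------------------------------------------------- #

@dataclass
class DensityMap:
    """A 3D scalar grid with physical pixel size and origin.

    ``grid`` is indexed ``[x, y, z]`` (float32); ``voxel_size`` is isotropic
    Å per voxel; ``origin`` is the Å offset of the *corner* of voxel
    (0, 0, 0), i.e. the centre of that voxel is ``origin + voxel_size/2``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 voxels per axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be a finite 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical Å coordinates of voxel centres along one axis."""
        n = self.grid.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def position_to_index(self, position: np.ndarray) -> np.ndarray:
        """Fractional voxel index whose centre is at ``position`` (Å)."""
        return (np.asarray(position, float) - self.origin) / self.voxel_size - 0.5


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map (modes 0, 1, 2) into a :class:`DensityMap`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"unsupported MRC mode field: {mode}")
    grid = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    nx, ny, nz = grid.shape
    vox = cell.a / nx
    for extent, n, name in ((cell.b, ny, "b"), (cell.c, nz, "c")):
        if not math.isclose(extent / n, vox, rel_tol=1e-3):
            raise MapFormatError(
                f"anisotropic voxel size (cell {name}={extent:.3f} over {n} voxels "
                f"vs {vox:.4f} Å from cell a) is not supported"
            )
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not np.all(np.isfinite(grid)):
        raise MapFormatError(f"map {path} contains non-finite values")
    return DensityMap(grid, vox, origin)


def write_map(density: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 mode 2 (little-endian float32)."""
    if not np.all(np.isfinite(density.grid)):
        raise ValueError("refusing to write a map with non-finite values")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(density.grid, dtype=np.float32))
    nx, ny, nz = density.grid.shape
    vs = density.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), density.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


# --------------------------------------------------------------------------- #
# Particle tables
# --------------------------------------------------------------------------- #

PARTICLE_COLUMNS = ["id", "x", "y", "z", "phi", "theta", "psi", "cc", "class"]


@dataclass
class ParticleTable:
    """Motive list: one row per particle.

    Columns: ``id`` (unique int), position ``x, y, z`` (Å), orientation
    ``phi, theta, psi`` (deg, Z-Y-Z, template->tomogram), ``cc`` (score in
    [-1, 1], NaN when unset), ``class`` (int label, NaN when unset).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"particle table missing columns: {missing}")
        df = df[PARTICLE_COLUMNS + [c for c in df.columns if c not in PARTICLE_COLUMNS]]
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate particle ids: {dup[:5]}")
        pos = df[["x", "y", "z"]].to_numpy(float)
        if len(df) and not np.all(np.isfinite(pos)):
            raise SchemaError("non-finite particle positions")
        if len(df):
            ang = np.array([
                normalize_euler(p, t, s)
                for p, t, s in df[["phi", "theta", "psi"]].to_numpy(float)
            ])
            df[["phi", "theta", "psi"]] = ang
        cc = df["cc"].to_numpy(float)
        if np.any((cc < -1 - 1e-9) | (cc > 1 + 1e-9)):
            raise SchemaError("cc scores outside [-1, 1]")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "ParticleTable":
        return cls(pd.DataFrame(columns=PARTICLE_COLUMNS))

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        eulers: np.ndarray | None = None,
        ids: Sequence[int] | None = None,
        cc: np.ndarray | None = None,
        class_label: np.ndarray | None = None,
        extra: dict | None = None,
    ) -> "ParticleTable":
        positions = np.atleast_2d(np.asarray(positions, float))
        n = len(positions)
        eulers = np.zeros((n, 3)) if eulers is None else np.atleast_2d(eulers)
        data = {
            "id": np.arange(n) if ids is None else np.asarray(ids),
            "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
            "phi": eulers[:, 0], "theta": eulers[:, 1], "psi": eulers[:, 2],
            "cc": np.full(n, np.nan) if cc is None else np.asarray(cc, float),
            "class": np.full(n, np.nan) if class_label is None else class_label,
        }
        if extra:
            data.update(extra)
        return cls(pd.DataFrame(data))

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(float)

    @property
    def eulers(self) -> np.ndarray:
        return self.df[["phi", "theta", "psi"]].to_numpy(float)

    def rotation_matrices(self) -> np.ndarray:
        if len(self) == 0:
            return np.zeros((0, 3, 3))
        return Rotation.from_euler("ZYZ", self.eulers, degrees=True).as_matrix()

    def with_updates(
        self,
        positions: np.ndarray | None = None,
        eulers: np.ndarray | None = None,
        cc: np.ndarray | None = None,
    ) -> "ParticleTable":
        df = self.df.copy()
        if positions is not None:
            df[["x", "y", "z"]] = np.asarray(positions, float)
        if eulers is not None:
            df[["phi", "theta", "psi"]] = np.asarray(eulers, float)
        if cc is not None:
            df["cc"] = np.asarray(cc, float)
        return ParticleTable(df)


def read_particles(path: str | Path) -> ParticleTable:
    """Read a tab-separated particle table (header line required)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"particle table {path} missing columns: {missing}")
    return ParticleTable(df)


def write_particles(table: ParticleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# --------------------------------------------------------------------------- #
# Geometry primitives
# --------------------------------------------------------------------------- #

@dataclass
class VesicleModel:
    """Spherical membrane model: stand-in for a segmented vesicle."""

    centre: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        if self.centre.shape != (3,):
            raise ValueError("centre must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance of points (n,3) to the spherical surface (Å)."""
        points = np.atleast_2d(points)
        return np.abs(np.linalg.norm(points - self.centre, axis=1) - self.radius)

    def outward_normal(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        d = points - self.centre
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise ValueError("normal undefined at the vesicle centre")
        return d / norms


@dataclass
class TiltGeometry:
    """Tilt-series geometry: the angular range sets the missing wedge."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    increment: float = 3.0
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be below tilt_max")
        if not self.increment > 0:
            raise ValueError("increment must be positive")
        if self.tilt_axis not in ("x", "y"):
            raise ValueError("tilt_axis must be one of the in-plane axes 'x' or 'y'")


# --------------------------------------------------------------------------- #
# Atomic models
# --------------------------------------------------------------------------- #

class EmptyModelError(ValueError):
    """Raised when a coordinate file holds no ATOM/HETATM records."""


@dataclass
class AtomicModel:
    """Flat table of atoms from PDB ATOM/HETATM records.

    Only the first altloc of each atom is kept on reading. Atoms are
    addressable by (chain, residue_number, atom_name).
    """

    serial: np.ndarray
    element: list[str]
    atom_name: list[str]
    residue_name: list[str]
    residue_number: np.ndarray
    chain: list[str]
    xyz: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atom coordinates")

    def __len__(self) -> int:
        return len(self.xyz)

    def select(
        self,
        chain: str | None = None,
        residue_numbers: Sequence[int] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms matching the given criteria."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= np.array([c == chain for c in self.chain])
        if residue_numbers is not None:
            resset = set(int(r) for r in residue_numbers)
            mask &= np.array([int(r) in resset for r in self.residue_number])
        if atom_names is not None:
            nameset = set(atom_names)
            mask &= np.array([a in nameset for a in self.atom_name])
        return mask

    def with_xyz(self, xyz: np.ndarray) -> "AtomicModel":
        return dataclasses.replace(self, xyz=np.asarray(xyz, float))


def _model_from_structure(st: gemmi.Structure) -> AtomicModel:
    st.remove_alternative_conformations()
    serial, element, atom_name, residue_name = [], [], [], []
    residue_number, chain, xyz, mass = [], [], [], []
    for model in st:
        for ch in model:
            for res in ch:
                for at in res:
                    serial.append(at.serial)
                    element.append(at.element.name)
                    atom_name.append(at.name)
                    residue_name.append(res.name)
                    residue_number.append(res.seqid.num)
                    chain.append(ch.name)
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
                    mass.append(at.element.weight)
        break  # first model only
    if not xyz:
        raise EmptyModelError("no ATOM/HETATM records found")
    return AtomicModel(
        serial=np.array(serial, dtype=int),
        element=element,
        atom_name=atom_name,
        residue_name=residue_name,
        residue_number=np.array(residue_number, dtype=int),
        chain=chain,
        xyz=np.array(xyz, dtype=float),
        mass=np.array(mass, dtype=float),
    )


def read_atomic_model(path: str | Path) -> AtomicModel:
    """Read the ATOM/HETATM subset of a PDB file (first model, first altloc)."""
    st = gemmi.read_pdb(str(path))
    return _model_from_structure(st)


def write_atomic_model(model: AtomicModel, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only)."""
    lines = []
    for i in range(len(model)):
        x, y, z = model.xyz[i]
        lines.append(
            "ATOM  {serial:>5d} {name:<4s}{res:>3s} {chain:1s}{resnum:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}".format(
                serial=int(model.serial[i]) % 100000,
                name=_pad_atom_name(model.atom_name[i]),
                res=model.residue_name[i][:3],
                chain=(model.chain[i] or "A")[:1],
                resnum=int(model.residue_number[i]),
                x=x, y=y, z=z,
                el=model.element[i][:2],
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pad_atom_name(name: str) -> str:
    # PDB columns 13-16: element right-aligned in 13-14 for 1-2 char elements
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}" if len(name) < 4 and not name[:1].isdigit() else f"{name:<4s}"


# --------------------------------------------------------------------------- #
# Domain assignment for hinge-flexible fitting
# --------------------------------------------------------------------------- #

@dataclass
class DomainAssignment:
    """Residue ranges for a three-domain (class II fusogen-like) ectodomain.

    ``domains`` maps domain name ('I', 'II', 'III', 'MPR') to an inclusive
    residue-number range. ``hinges`` maps a domain pair ('I-II', 'I-III') to
    the hinge residue numbers joining them; hinge residues move with the
    distal domain of the pair during flexible fitting.
    """

    domains: dict[str, tuple[int, int]]
    hinges: dict[str, list[int]]

    def __post_init__(self) -> None:
        ranges = sorted(self.domains.values())
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if a1 >= b0:
                raise ValueError(f"overlapping domain ranges {(a0, a1)} and {(b0, b1)}")
        for key, residues in self.hinges.items():
            parts = key.split("-")
            if len(parts) != 2 or any(p not in self.domains for p in parts):
                raise ValueError(f"hinge key {key!r} must join two assigned domains")
            lo = min(self.domains[p][0] for p in parts)
            hi = max(self.domains[p][1] for p in parts)
            for r in residues:
                if not lo <= r <= hi:
                    raise ValueError(
                        f"hinge residue {r} lies outside the domains it joins ({key})"
                    )

    def residues(self, domain: str) -> tuple[int, int]:
        return self.domains[domain]

    def domain_mask(self, model: AtomicModel, domain: str) -> np.ndarray:
        lo, hi = self.domains[domain]
        return (model.residue_number >= lo) & (model.residue_number <= hi)


# --------------------------------------------------------------------------- #
# FSC curves and emPAI tables
# --------------------------------------------------------------------------- #

@dataclass
class FSCCurve:
    """Fourier shell correlation: shell-centre frequencies (1/Å) vs values."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have equal length")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies, "fsc": self.values})

    @classmethod
    def from_file(cls, path: str | Path) -> "FSCCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["frequency"].to_numpy(), df["fsc"].to_numpy())

    def to_file(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class EmpaiTable:
    """Protein -> emPAI table for one preparation; NaN empai means not detected."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("protein", "empai"):
            if col not in self.df.columns:
                raise SchemaError(f"emPAI table missing column {col!r}")
        vals = self.df["empai"].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("emPAI values must be non-negative")
        self.df = self.df.reset_index(drop=True)
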