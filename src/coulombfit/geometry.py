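"""Nuclei, coordinate systems and the exact internuclear Coulomb repulsion.

Within the Born-Oppenheimer picture the potential energy for nuclear motion
is ``V = E_el + V_nu`` with ``V_nu = sum_{i<j} Z_i Z_j / R_ij`` in atomic
units.  This module provides the geometry descriptors used throughout the
package (Cartesian frames, a single internuclear distance, Jacobi
coordinates, bond-distance triples and torsion scans) and evaluates
``V_nu`` exactly for each of them.

Internal units are bohr for lengths, degrees for angles and hartree for
energies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "AtomSpec",
    "MolecularFrame",
    "CoordinateSpec",
    "element_data",
    "pairwise_distances",
    "nuclear_repulsion",
    "jacobi_to_distances",
    "bond_triple_to_distances",
    "bond_triple_to_angle",
    "torsion_frame",
    "read_xyz",
    "write_xyz",
]

#: pairwise distances closer than this (bohr) are treated as coincident
COINCIDENT_TOL = 1e-12

#: slack allowed on the triangle inequality for collinear bond triples (bohr)
COLLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when two nuclei coincide or a geometry is otherwise singular."""


def _load_elements() -> dict:
    with resources.files("coulombfit.data").joinpath("elements.json").open() as fh:
        return json.load(fh)


_ELEMENTS = _load_elements()


def element_data(symbol: str) -> dict:
    """Return ``{"Z": ..., "mass": ...}`` for an element symbol."""
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None


@dataclass(frozen=True)
class AtomSpec:
    """A nucleus: element label, nuclear charge and mass.

    ``Z`` is the nuclear charge in elementary charges and ``mass`` the
    atomic mass in unified amu.  The mass default is the standard atomic
    weight; override it for isotopes or for nuclear (electron-stripped)
    masses when computing rovibrational reduced masses of ions.
    """

    symbol: str
    Z: float
    mass: float

    def __post_init__(self):
        if not self.Z > 0:
            raise ValueError(f"nuclear charge must be positive, got {self.Z}")
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")

    @classmethod
    def from_symbol(cls, symbol: str, mass: float | None = None) -> "AtomSpec":
        data = element_data(symbol)
        return cls(symbol=symbol, Z=float(data["Z"]),
                   mass=float(mass if mass is not None else data["mass"]))


@dataclass
class MolecularFrame:
    """An ordered set of nuclei with Cartesian positions in bohr."""

    atoms: tuple[AtomSpec, ...]
    positions: np.ndarray  # (n_atoms, 3), bohr

    def __post_init__(self):
        self.atoms = tuple(self.atoms)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atoms), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.atoms)} atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.Z for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def translated(self, shift) -> "MolecularFrame":
        return MolecularFrame(self.atoms, self.positions + np.asarray(shift))

    def rotated(self, rotation_matrix) -> "MolecularFrame":
        return MolecularFrame(self.atoms, self.positions @ np.asarray(rotation_matrix).T)


def pairwise_distances(frame: MolecularFrame) -> list[tuple[int, int, float]]:
    """All internuclear distances ``(i, j, R_ij)`` with ``i < j``, in bohr.

    Raises :class:`DegenerateGeometryError` if any two nuclei coincide.
    """
    pos = frame.positions
    n = len(frame.atoms)
    if n < 2:
        raise ValueError("need at least two atoms for pairwise distances")
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d <= COINCIDENT_TOL:
                raise DegenerateGeometryError(
                    f"atoms {i} and {j} coincide (distance {d:g} bohr)")
            out.append((i, j, d))
    return out


def nuclear_repulsion(frame_or_distances, charges=None) -> float:
    """Exact Coulomb repulsion ``V_nu = sum_{i<j} Z_i Z_j / R_ij`` in hartree.

    Accepts either a :class:`MolecularFrame` or an iterable of
    ``(i, j, distance)`` tuples together with a sequence of charges.
    """
    if isinstance(frame_or_distances, MolecularFrame):
        dists = pairwise_distances(frame_or_distances)
        charges = frame_or_distances.charges
    else:
        dists = list(frame_or_distances)
        if charges is None:
            raise ValueError("charges are required with an explicit distance list")
        charges = np.asarray(charges, dtype=float)
    v = 0.0
    for i, j, d in dists:
        if d <= COINCIDENT_TOL:
            raise DegenerateGeometryError(
                f"zero distance between atoms {i} and {j}: V_nu is singular")
        v += charges[i] * charges[j] / d
    return v


def jacobi_to_distances(R: float, r: float, theta: float,
                        diatom_masses: tuple[float, float],
                        assignment: str = "A") -> tuple[float, float, float]:
    """Convert Jacobi coordinates to the three internuclear distances.

    The diatom A-B has bond length ``r``; ``R`` is the distance from the
    diatom's centre of mass X to the projectile C, and ``theta`` (degrees,
    in [0, 180]) the angle at X between C and one end of the diatom.
    ``assignment`` selects which end theta=0 points toward: ``"A"`` (first
    diatom atom) or ``"B"``.  A sits at ``f*r`` from X with
    ``f = m_B / (m_A + m_B)``, B at ``(1-f)*r`` on the opposite side.

    Returns ``(d_AB, d_CA, d_CB)`` in bohr.
    """
    if not (R > 0 and r > 0):
        raise ValueError("Jacobi R and r must be positive")
    if not (0.0 <= theta <= 180.0):
        raise ValueError(f"theta must be in [0, 180] degrees, got {theta}")
    if assignment not in ("A", "B"):
        raise ValueError("assignment must be 'A' or 'B'")
    m_a, m_b = diatom_masses
    f = m_b / (m_a + m_b)     # A's fractional arm
    ra = f * r                # |X - A|
    rb = (1.0 - f) * r        # |X - B|
    th = math.radians(theta)
    if assignment == "B":
        th = math.pi - th
    # law of cosines at X; A and B lie on opposite sides of X
    d_ca = math.sqrt(R * R + ra * ra - 2.0 * R * ra * math.cos(th))
    d_cb = math.sqrt(R * R + rb * rb - 2.0 * R * rb * math.cos(math.pi - th))
    return r, d_ca, d_cb


def jacobi_frame(R: float, r: float, theta: float,
                 atoms: tuple[AtomSpec, AtomSpec, AtomSpec],
                 assignment: str = "A") -> MolecularFrame:
    """Explicit Cartesian frame (A, B, C) realising the Jacobi coordinates."""
    m_a, m_b = atoms[0].mass, atoms[1].mass
    f = m_b / (m_a + m_b)
    th = math.radians(theta if assignment == "A" else 180.0 - theta)
    pos = np.array([
        [f * r, 0.0, 0.0],
        [-(1.0 - f) * r, 0.0, 0.0],
        [R * math.cos(th), R * math.sin(th), 0.0],
    ])
    return MolecularFrame(atoms, pos)


def bond_triple_to_distances(r1: float, r2: float, r3: float,
                             tol: float = COLLINEAR_TOL) -> tuple[float, float, float]:
    """Validate a triangle of bond distances and return it unchanged.

    The three distances are the pairs (0,1), (1,2) and (0,2) of a triatomic.
    Collinear arrangements (one side equal to the sum of the other two) are
    accepted within ``tol`` bohr; worse violations of the triangle
    inequality raise :class:`DegenerateGeometryError`.
    """
    sides = (r1, r2, r3)
    if any(s <= 0 for s in sides):
        raise ValueError(f"all bond distances must be positive, got {sides}")
    for k in range(3):
        others = sides[(k + 1) % 3] + sides[(k + 2) % 3]
        if sides[k] > others + tol:
            raise DegenerateGeometryError(
                f"triangle inequality violated: side {sides[k]:g} exceeds "
                f"sum of others {others:g} by more than {tol:g} bohr")
    return sides


def bond_triple_to_angle(r1: float, r2: float, r3: float) -> float:
    """Included angle (degrees) between sides r1 and r2, opposite r3.

    Used for fixed-angle slices through (r1, r2, r3) surfaces.
    """
    bond_triple_to_distances(r1, r2, r3)
    c = (r1 * r1 + r2 * r2 - r3 * r3) / (2.0 * r1 * r2)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    u = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def torsion_frame(template: MolecularFrame,
                  dihedral_atoms: tuple[int, int, int, int],
                  phi: float,
                  rotate_atoms: tuple[int, ...] | None = None) -> MolecularFrame:
    """Rigidly rotate part of a frame about a dihedral axis by ``phi`` degrees.

    ``dihedral_atoms = (p, a, b, q)`` defines the torsion; the rotation axis
    is the a-b bond.  ``rotate_atoms`` lists the atoms to rotate (default:
    atom ``q`` only).  Bond lengths within the rotated group are preserved
    exactly (rigid rotation).
    """
    p, a, b, q = dihedral_atoms
    if a == b:
        raise ValueError("dihedral axis atoms must be distinct")
    pos = template.positions.copy()
    axis = pos[b] - pos[a]
    if np.linalg.norm(axis) <= COINCIDENT_TOL:
        raise DegenerateGeometryError("dihedral axis atoms coincide")
    rot = _rotation_about_axis(axis, phi)
    group = rotate_atoms if rotate_atoms is not None else (q,)
    for k in group:
        pos[k] = pos[a] + rot @ (pos[k] - pos[a])
    return MolecularFrame(template.atoms, pos)


def read_xyz(path, masses: dict | None = None) -> MolecularFrame:
    """Read a standard XYZ file (angstrom) into a :class:`MolecularFrame`.

    Format: atom count line, comment line, then ``element x y z`` rows.
    ``masses`` optionally overrides the standard atomic weight per symbol.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"invalid XYZ count line: {lines[0]!r}") from None
    atoms, pos = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ row: {ln!r}")
        sym = parts[0]
        m = masses.get(sym) if masses else None
        atoms.append(AtomSpec.from_symbol(sym, mass=m))
        pos.append([float(x) for x in parts[1:4]])
    if len(atoms) != n:
        raise ValueError(f"XYZ declares {n} atoms but has {len(atoms)} rows")
    return MolecularFrame(tuple(atoms), np.asarray(pos) * ANGSTROM_TO_BOHR)


def write_xyz(frame: MolecularFrame, path, comment: str = "") -> None:
    """Write a frame to standard XYZ (angstrom)."""
    pos = frame.positions * BOHR_TO_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{len(frame.atoms)}\n{comment}\n")
        for atom, xyz in zip(frame.atoms, pos):
            fh.write(f"{atom.symbol} {xyz[0]:.12f} {xyz[1]:.12f} {xyz[2]:.12f}\n")


# ---------------------------------------------------------------------------
# Coordinate systems

_KIND_COLUMNS = {
    "diatomic_R": ("R",),
    "jacobi_3d": ("R", "r", "theta"),
    "bond_triple": ("r1", "r2", "r3"),
    "torsion": ("phi",),
}


@dataclass
class CoordinateSpec:
    """Declares how coordinate vectors map to molecular geometries.

    ``kind`` is one of ``diatomic_R`` (single internuclear distance),
    ``jacobi_3d`` (R, r, theta with atoms ordered diatom-A, diatom-B,
    projectile), ``bond_triple`` (three internuclear distances), ``torsion``
    (a dihedral scan of a rigid template) or ``cartesian`` (flattened
    positions).  Lengths are in bohr, angles in degrees.

    ``fixed_params`` carries per-kind constants: for ``torsion`` the keys
    ``template`` (MolecularFrame), ``dihedral_atoms`` and ``rotate_atoms``;
    for ``jacobi_3d`` the optional key ``assignment`` ("A" or "B") selecting
    which diatom end theta=0 points toward — the choice is physically a
    convention and is therefore an explicit parameter.
    """

    kind: str
    atoms: tuple[AtomSpec, ...]
    fixed_params: dict = field(default_factory=dict)
    angle_unit: str = "degree"

    def __post_init__(self):
        self.atoms = tuple(self.atoms)
        if self.kind not in (*_KIND_COLUMNS, "cartesian"):
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if self.kind in ("jacobi_3d", "bond_triple") and len(self.atoms) != 3:
            raise ValueError(f"{self.kind} requires exactly 3 atoms")
        if self.kind == "diatomic_R" and len(self.atoms) != 2:
            raise ValueError("diatomic_R requires exactly 2 atoms")
        if self.kind == "torsion":
            for key in ("template", "dihedral_atoms"):
                if key not in self.fixed_params:
                    raise ValueError(f"torsion spec needs fixed_params[{key!r}]")

    @property
    def n_dims(self) -> int:
        if self.kind == "cartesian":
            return 3 * len(self.atoms)
        return len(_KIND_COLUMNS[self.kind])

    @property
    def columns(self) -> tuple[str, ...]:
        if self.kind == "cartesian":
            return tuple(f"{ax}{i}" for i in range(len(self.atoms)) for ax in "xyz")
        return _KIND_COLUMNS[self.kind]

    def frame(self, coords) -> MolecularFrame:
        """Explicit Cartesian frame for one coordinate vector (where defined)."""
        coords = np.atleast_1d(np.asarray(coords, dtype=float))
        if self.kind == "cartesian":
            return MolecularFrame(self.atoms, coords.reshape(-1, 3))
        if self.kind == "torsion":
            return torsion_frame(self.fixed_params["template"],
                                 self.fixed_params["dihedral_atoms"],
                                 float(coords[0]),
                                 self.fixed_params.get("rotate_atoms"))
        if self.kind == "jacobi_3d":
            return jacobi_frame(coords[0], coords[1], coords[2], self.atoms,
                                self.fixed_params.get("assignment", "A"))
        raise ValueError(f"no Cartesian frame construction for kind {self.kind!r}")

    def vnu(self, coords) -> np.ndarray:
        """Exact Coulomb repulsion (hartree) for an (n, d) coordinate array."""
        X = np.asarray(coords, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, self.n_dims)
        if X.shape[1] != self.n_dims:
            raise ValueError(
                f"coordinate dimensionality {X.shape[1]} does not match "
                f"kind {self.kind!r} ({self.n_dims})")
        Z = np.array([a.Z for a in self.atoms])
        if self.kind == "diatomic_R":
            R = X[:, 0]
            if np.any(R <= 0):
                raise DegenerateGeometryError("R must be positive for V_nu")
            return Z[0] * Z[1] / R
        if self.kind == "bond_triple":
            out = np.empty(len(X))
            for k, (r1, r2, r3) in enumerate(X):
                bond_triple_to_distances(r1, r2, r3)
                out[k] = Z[0] * Z[1] / r1 + Z[1] * Z[2] / r2 + Z[0] * Z[2] / r3
            return out
        if self.kind == "jacobi_3d":
            masses = (self.atoms[0].mass, self.atoms[1].mass)
            assignment = self.fixed_params.get("assignment", "A")
            out = np.empty(len(X))
            for k, (R, r, th) in enumerate(X):
                d_ab, d_ca, d_cb = jacobi_to_distances(R, r, th, masses, assignment)
                out[k] = Z[0] * Z[1] / d_ab + Z[2] * Z[0] / d_ca + Z[2] * Z[1] / d_cb
            return out
        # torsion / cartesian: build frames
        out = np.empty(len(X))
        for k, row in enumerate(X):
            out[k] = nuclear_repulsion(self.frame(row))
        return out
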