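"""Geometry/energy tables and the Coulomb subtraction at their core.

An :class:`EnergyTable` holds coordinate vectors together with the potential
energy ``V``, the electronic energy ``E_el`` and the exact nuclear repulsion
``V_nu`` (all hartree internally).  The central operations are

* :func:`subtract_nuclear` — fill ``E_el = V - V_nu`` from ``V``,
* :func:`add_nuclear` — fill ``V = E_el + V_nu`` from ``E_el``,
* :func:`add_united_atom` — prepend the finite R=0 electronic energy,
* :func:`split_train_test` — reproducible train/test partitions, including
  a stratified strategy that over-samples the steep repulsive wall.

CSV I/O uses ``#``-prefixed metadata headers declaring units, coordinate
kind and atoms, so that tables written in cm^-1/angstrom and in
hartree/bohr load to identical internal tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (ANGSTROM_TO_BOHR, HARTREE_TO_INVCM, cm_to_hartree,
                        hartree_to_cm)
from .geometry import AtomSpec, CoordinateSpec

__all__ = [
    "EnergyTable",
    "SplitSpec",
    "subtract_nuclear",
    "add_nuclear",
    "add_united_atom",
    "split_train_test",
    "read_table",
    "write_table",
]

#: V = E_el + V_nu consistency tolerance at load time, cm^-1
_CONSISTENCY_TOL_CM = 1e-6


class EnergyTable:
    """A table of geometries with potential and/or electronic energies.

    Parameters
    ----------
    coordinate_spec :
        Declares the coordinate system; its atoms supply the nuclear charges
        used for ``V_nu``.
    coords :
        (n, d) array in internal units (bohr / degrees).
    V, Eel :
        Energies in hartree; at least one must be given per record.
    is_united_atom :
        Boolean flags; united-atom records carry ``E_el`` only (``V`` and
        ``V_nu`` are undefined at R = 0) and are always forced into
        training sets.
    """

    def __init__(self, coordinate_spec: CoordinateSpec, coords,
                 V=None, Eel=None, is_united_atom=None,
                 state_label: int = 0, provenance: str = ""):
        self.coordinate_spec = coordinate_spec
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords.reshape(-1, coordinate_spec.n_dims)
        if coords.shape[1] != coordinate_spec.n_dims:
            raise ValueError("coordinate dimensionality mismatch")
        n = len(coords)
        if n and len(np.unique(coords.round(12), axis=0)) != n:
            raise ValueError("duplicate coordinate vectors in table")

        ua = (np.zeros(n, dtype=bool) if is_united_atom is None
              else np.asarray(is_united_atom, dtype=bool))
        V = np.full(n, np.nan) if V is None else np.asarray(V, dtype=float)
        Eel = np.full(n, np.nan) if Eel is None else np.asarray(Eel, dtype=float)
        if np.any(np.isnan(V) & np.isnan(Eel)):
            raise ValueError("every record needs at least one of V, E_el")
        if np.any(ua & ~np.isnan(V)):
            raise ValueError("united-atom records must not carry V (undefined at R=0)")

        vnu = np.full(n, np.nan)
        if np.any(~ua):
            vnu[~ua] = coordinate_spec.vnu(coords[~ua])

        both = (~ua) & ~np.isnan(V) & ~np.isnan(Eel)
        if np.any(both):
            dev = np.abs(V[both] - Eel[both] - vnu[both]) * HARTREE_TO_INVCM
            if dev.max() > _CONSISTENCY_TOL_CM:
                raise ValueError(
                    f"V != E_el + V_nu by up to {dev.max():.3g} cm^-1 "
                    f"(tolerance {_CONSISTENCY_TOL_CM} cm^-1)")

        df = pd.DataFrame(coords, columns=list(coordinate_spec.columns))
        df["V"] = V
        df["Eel"] = Eel
        df["Vnu"] = vnu
        df["is_united_atom"] = ua
        self.df = df
        self.state_label = state_label
        self.provenance = provenance

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[list(self.coordinate_spec.columns)].to_numpy()

    @property
    def V(self) -> np.ndarray:
        return self.df["V"].to_numpy()

    @property
    def Eel(self) -> np.ndarray:
        return self.df["Eel"].to_numpy()

    @property
    def Vnu(self) -> np.ndarray:
        return self.df["Vnu"].to_numpy()

    @property
    def is_united_atom(self) -> np.ndarray:
        return self.df["is_united_atom"].to_numpy()

    def V_cm(self) -> np.ndarray:
        return hartree_to_cm(self.V)

    def Eel_cm(self) -> np.ndarray:
        return hartree_to_cm(self.Eel)

    def copy_with(self, **overrides) -> "EnergyTable":
        kw = dict(coordinate_spec=self.coordinate_spec, coords=self.coords,
                  V=self.V, Eel=self.Eel, is_united_atom=self.is_united_atom,
                  state_label=self.state_label, provenance=self.provenance)
        kw.update(overrides)
        return EnergyTable(**kw)


def subtract_nuclear(table: EnergyTable) -> EnergyTable:
    """Fill ``E_el = V - V_nu`` for every non-united-atom record.

    ``V`` is retained; existing ``E_el`` values on united-atom records are
    kept as-is.
    """
    ua = table.is_united_atom
    if np.any(~ua & np.isnan(table.V)):
        raise ValueError("subtract_nuclear requires V on every non-united-atom record")
    Eel = table.Eel.copy()
    Eel[~ua] = table.V[~ua] - table.Vnu[~ua]
    return table.copy_with(Eel=Eel)


def add_nuclear(table: EnergyTable) -> EnergyTable:
    """Fill ``V = E_el + V_nu``; united-atom records keep V undefined."""
    ua = table.is_united_atom
    if np.any(~ua & np.isnan(table.Eel)):
        raise ValueError("add_nuclear requires E_el on every non-united-atom record")
    V = table.V.copy()
    V[~ua] = table.Eel[~ua] + table.Vnu[~ua]
    return table.copy_with(V=V)


def add_united_atom(table: EnergyTable, E_ua="hydrogenic",
                    n_electrons: int | None = None) -> EnergyTable:
    """Prepend the united-atom (R = 0) electronic-energy record.

    ``E_ua`` is the electronic energy at the united-atom limit in hartree,
    or the string ``"hydrogenic"`` to use ``-(Z1+Z2)^2 / 2`` — valid only
    for one-electron systems (declare ``n_electrons=1``).  The record is
    flagged ``is_united_atom`` and is always assigned to training splits;
    scheme-A fits ignore it, since V diverges at R = 0.
    """
    if table.coordinate_spec.kind != "diatomic_R":
        raise ValueError("united-atom augmentation applies to diatomic_R tables only")
    if isinstance(E_ua, str):
        if E_ua != "hydrogenic":
            raise ValueError(f"unknown united-atom rule {E_ua!r}")
        if n_electrons != 1:
            raise ValueError(
                "the hydrogenic united-atom energy -(Z1+Z2)^2/2 is valid only "
                "for one-electron systems; pass n_electrons=1 to confirm")
        z = sum(a.Z for a in table.coordinate_spec.atoms)
        e_ua = -0.5 * z * z
    else:
        e_ua = float(E_ua)
    coords = np.vstack([[0.0], table.coords])
    V = np.concatenate([[np.nan], table.V])
    Eel = np.concatenate([[e_ua], table.Eel])
    ua = np.concatenate([[True], table.is_united_atom])
    return EnergyTable(table.coordinate_spec, coords, V=V, Eel=Eel,
                       is_united_atom=ua, state_label=table.state_label,
                       provenance=table.provenance)


@dataclass
class SplitSpec:
    """Train/test partition recipe.

    ``strategy`` is ``random``, ``manual`` (explicit training indices) or
    ``stratified_energy``.  The stratified strategy emulates hand-selected
    training sets with increased density in the steep repulsive region: it
    ranks records by the local finite-difference slope |dV/dx| along the
    first coordinate and guarantees that at least ``ceil(density_boost)``
    records of the top-slope decile land in the training set (default: the
    whole decile).
    """

    train_fraction: float = 0.8
    strategy: str = "random"
    seed: int | None = None
    manual_indices: tuple | None = None
    density_boost: float | None = None

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.strategy not in ("random", "manual", "stratified_energy"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")
        if self.strategy == "manual" and self.manual_indices is None:
            raise ValueError("manual strategy requires manual_indices")
        if self.strategy in ("random", "stratified_energy") and self.seed is None:
            raise ValueError(f"{self.strategy} strategy requires a seed")


def _top_slope_decile(table: EnergyTable, free: np.ndarray) -> np.ndarray:
    """Indices (within `free`) of the top decile by local |dE/dx| slope."""
    x = table.coords[free, 0]
    y = table.V[free]
    if np.all(np.isnan(y)):
        y = table.Eel[free]
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    slope = np.abs(np.gradient(ys, xs))
    n_dec = max(1, math.ceil(0.1 * len(free)))
    top = order[np.argsort(slope)[::-1][:n_dec]]
    return free[top]


def split_train_test(table: EnergyTable, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test) index arrays.

    United-atom records are forced into training.  The training size over
    the remaining records is ``floor(train_fraction * n)``, which reproduces
    the conventional printed counts (81 records at 9:1 give 72/9).
    Deterministic for a fixed seed.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty table")
    forced = np.flatnonzero(table.is_united_atom)
    free = np.flatnonzero(~table.is_united_atom)

    if spec.strategy == "manual":
        manual = np.asarray(spec.manual_indices, dtype=int)
        if np.any(manual < 0) or np.any(manual >= n):
            raise IndexError("manual_indices out of range")
        train = np.unique(np.concatenate([manual, forced]))
        test = np.setdiff1d(np.arange(n), train)
    else:
        rng = np.random.default_rng(spec.seed)
        n_train = int(math.floor(spec.train_fraction * len(free)))
        if spec.strategy == "random":
            perm = rng.permutation(free)
            train = np.sort(np.concatenate([perm[:n_train], forced]))
            test = np.sort(perm[n_train:])
        else:  # stratified_energy
            decile = _top_slope_decile(table, free)
            boost = len(decile) if spec.density_boost is None else \
                min(len(decile), math.ceil(spec.density_boost))
            picked = rng.permutation(decile)[:boost]
            rest = np.setdiff1d(free, picked)
            n_more = max(0, n_train - len(picked))
            perm = rng.permutation(rest)
            train = np.sort(np.concatenate([picked, perm[:n_more], forced]))
            test = np.sort(perm[n_more:])
    if len(train) == 0 or len(test) == 0:
        raise ValueError(f"degenerate split: {len(train)} train / {len(test)} test")
    return train, test


# ---------------------------------------------------------------------------
# CSV I/O

_ENERGY_FACTORS = {"cm-1": 1.0 / HARTREE_TO_INVCM, "hartree": 1.0}
_COORD_FACTORS = {"angstrom": ANGSTROM_TO_BOHR, "bohr": 1.0, "degree": 1.0}


def _coord_unit_factors(spec: CoordinateSpec, coord_unit: str) -> np.ndarray:
    """Per-column conversion factors from file units to internal units."""
    if coord_unit not in ("angstrom", "bohr"):
        raise ValueError(f"unparseable coord_unit {coord_unit!r}")
    length = _COORD_FACTORS[coord_unit]
    factors = []
    for col in spec.columns:
        factors.append(1.0 if col in ("theta", "phi") else length)
    return np.asarray(factors)


def write_table(table: EnergyTable, path, coord_unit: str = "angstrom",
                energy_unit: str = "cm-1", format: str = "csv") -> None:
    """Write a table as CSV with ``#`` metadata headers (lossless)."""
    if format != "csv":
        raise ValueError(f"unsupported table format {format!r}")
    if energy_unit not in _ENERGY_FACTORS:
        raise ValueError(f"unparseable energy_unit {energy_unit!r}")
    e_fac = 1.0 / _ENERGY_FACTORS[energy_unit]   # hartree -> file unit
    c_fac = 1.0 / _coord_unit_factors(table.coordinate_spec, coord_unit)
    spec = table.coordinate_spec
    cols = list(spec.columns)
    with open(path, "w") as fh:
        fh.write("# coulombfit energy table\n")
        fh.write(f"# kind={spec.kind}\n")
        fh.write(f"# atoms={','.join(a.symbol for a in spec.atoms)}\n")
        fh.write(f"# coord_unit={coord_unit}\n")
        fh.write(f"# energy_unit={energy_unit}\n")
        fh.write(f"# state_label={table.state_label}\n")
        fh.write(",".join(cols + ["V", "Eel", "is_united_atom"]) + "\n")
        coords = table.coords * c_fac
        for k in range(len(table)):
            row = [f"{v:.17g}" for v in coords[k]]
            for val in (table.V[k] * e_fac, table.Eel[k] * e_fac):
                row.append("" if np.isnan(val) else f"{val:.17g}")
            row.append(str(int(table.is_united_atom[k])))
            fh.write(",".join(row) + "\n")


def read_table(path, coordinate_spec: CoordinateSpec | None = None,
               format: str = "csv") -> EnergyTable:
    """Read a CSV energy table written by :func:`write_table`.

    The metadata header declares the coordinate kind, atoms and units; a
    ``coordinate_spec`` argument overrides the reconstructed spec (required
    for ``torsion`` and ``cartesian`` kinds, whose fixed parameters cannot
    be serialised in the header).
    """
    if format != "csv":
        raise ValueError(f"unsupported table format {format!r}")
    meta: dict[str, str] = {}
    header: list[str] | None = None
    data_rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
            else:
                data_rows.append((lineno, line.split(",")))
    if header is None:
        raise ValueError(f"no column header found in {path}")

    if coordinate_spec is None:
        kind = meta.get("kind")
        if kind is None:
            raise ValueError("missing 'kind' metadata and no coordinate_spec given")
        if kind in ("torsion", "cartesian"):
            raise ValueError(
                f"kind {kind!r} requires an explicit coordinate_spec "
                "(fixed parameters are not stored in the CSV header)")
        atoms = tuple(AtomSpec.from_symbol(s)
                      for s in meta.get("atoms", "").split(",") if s)
        coordinate_spec = CoordinateSpec(kind, atoms)

    cols = list(coordinate_spec.columns)
    for col in cols:
        if col not in header:
            raise ValueError(f"missing coordinate column {col!r} in {path}")
    if "V" not in header and "Eel" not in header:
        raise ValueError("table must contain a V and/or an Eel column")

    coord_unit = meta.get("coord_unit", "angstrom")
    energy_unit = meta.get("energy_unit", "cm-1")
    if energy_unit not in _ENERGY_FACTORS:
        raise ValueError(f"unparseable energy_unit {energy_unit!r}")
    e_fac = _ENERGY_FACTORS[energy_unit]
    c_fac = _coord_unit_factors(coordinate_spec, coord_unit)

    idx = {name: header.index(name) for name in header}
    n_cols = len(header)
    coords, V, Eel, ua = [], [], [], []

    def _grab(parts, name, lineno, default=np.nan):
        if name not in idx:
            return default
        cell = parts[idx[name]].strip()
        if cell == "":
            return default
        try:
            return float(cell)
        except ValueError:
            raise ValueError(
                f"malformed value {cell!r} for column {name!r} "
                f"on line {lineno} of {path}") from None

    for lineno, parts in data_rows:
        if len(parts) != n_cols:
            raise ValueError(
                f"malformed row on line {lineno} of {path}: expected "
                f"{n_cols} fields, got {len(parts)}")
        coords.append([_grab(parts, c, lineno) for c in cols])
        V.append(_grab(parts, "V", lineno))
        Eel.append(_grab(parts, "Eel", lineno))
        ua.append(bool(int(_grab(parts, "is_united_atom", lineno, 0.0))))

    coords = np.asarray(coords) * c_fac
    return EnergyTable(coordinate_spec, coords,
                       V=np.asarray(V) * e_fac, Eel=np.asarray(Eel) * e_fac,
                       is_united_atom=ua,
                       state_label=int(meta.get("state_label", 0)),
                       provenance=str(path))
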