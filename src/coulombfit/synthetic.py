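"""Model datasets with the structure real ab initio energy tables possess.

The diatomic model is built around the defining contrast of the Coulomb
subtraction: the electronic energy E_el(R) rises smoothly and monotonically
from the united-atom limit E_ua at R = 0 to the separated-atom limit E_sep,
while the potential V = E_el + Z1 Z2 / R is singular at the origin and has
a single well.  The closed form is

    E_el(R) = E_sep - (E_sep - E_ua) (1 + aR) e^{-aR} - q * g(R)
    g(R)    = (1 - e^{-(bR)^3}) / R

(all atomic units).  The first part interpolates the two limits with zero
slope at R = 0 (no united-atom cusp).  The second part is a screened ionic
term: for a charged one-electron system the electronic energy approaches
the separated-atom limit as E_sep - q/R (the Coulomb 1/R of V_nu must
cancel at long range for an ion), and without it V would never dip below
the dissociation asymptote and the curve would support no bound states.
g rises from 0 at R = 0 (cubically flat, preserving the united-atom limit
and monotonicity) to 1/R at long range.  With the ``h2plus-like`` preset
(E_ua = -2, E_sep = -0.5, a = 1.5/bohr, q = 1, b = 0.5/bohr) the resulting
well is ~26,000 cm^-1 deep near 2.2 bohr — the same order as the real
one-electron cation it emulates, though no attempt is made to match
literature energies.

Triatomic surfaces are sums of pairwise diatomic models over the three
internuclear distances plus an optional Gaussian three-body term in Jacobi
coordinates; torsion curves are low-order Fourier series in the dihedral
riding on the exact V_nu of a rigid rotating template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, HARTREE_TO_INVCM
from .dataset import EnergyTable
from .geometry import (AtomSpec, CoordinateSpec, MolecularFrame,
                       jacobi_to_distances)

__all__ = ["ModelDiatomicSpec", "ModelTriatomicSpec", "TorsionSpec",
           "generate_diatomic_table", "generate_jacobi_table",
           "generate_torsion_table", "add_noise",
           "h2plus_like", "he2h_like", "ethane_like", "ethane_frame"]


@dataclass
class ModelDiatomicSpec:
    """Closed-form diatomic electronic-energy model (atomic units).

    ``q_lr`` is the long-range charge product (Z1*Z2 for a one-electron
    cation, 0 for a neutral-like pure-exponential approach) and ``b`` the
    screening rate of the ionic term.
    """

    E_ua: float = -2.0          # united-atom electronic energy, hartree
    E_sep: float = -0.5         # separated-atom electronic energy, hartree
    a: float = 1.5              # exponential decay rate, 1/bohr
    Z1: float = 1.0
    Z2: float = 1.0
    q_lr: float = 0.0           # long-range charge product (ionic tail)
    b: float = 0.5              # ionic screening rate, 1/bohr
    R_min: float = 0.026        # grid start, angstrom
    R_max: float = 10.583       # grid end, angstrom
    n_points: int = 401
    symbols: tuple = ("H", "H")

    def __post_init__(self):
        if not self.E_ua < self.E_sep:
            raise ValueError("E_ua must lie below E_sep")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("decay rates must be positive")
        if self.R_min <= 0:
            raise ValueError("R grid must exclude R = 0; the united-atom "
                             "record is added via dataset.add_united_atom")

    def electronic_energy(self, R_bohr) -> np.ndarray:
        """E_el(R) in hartree; E_el(0) = E_ua, E_el(inf) = E_sep."""
        R = np.asarray(R_bohr, dtype=float)
        base = self.E_sep - (self.E_sep - self.E_ua) * (1.0 + self.a * R) \
            * np.exp(-self.a * R)
        if self.q_lr:
            with np.errstate(invalid="ignore", divide="ignore"):
                g = np.where(R > 0,
                             (1.0 - np.exp(-(self.b * R) ** 3)) / np.where(R > 0, R, 1.0),
                             0.0)
            base = base - self.q_lr * g
        return base

    def potential(self, R_bohr) -> np.ndarray:
        """V(R) = E_el + Z1 Z2 / R in hartree."""
        R = np.asarray(R_bohr, dtype=float)
        return self.electronic_energy(R) + self.Z1 * self.Z2 / R

    def atoms(self) -> tuple[AtomSpec, AtomSpec]:
        return (AtomSpec.from_symbol(self.symbols[0]),
                AtomSpec.from_symbol(self.symbols[1]))


def h2plus_like() -> ModelDiatomicSpec:
    """Preset emulating the ground-state one-electron cation curve:
    401 points on [0.026, 10.583] angstrom, hydrogenic limits, ionic tail."""
    return ModelDiatomicSpec(E_ua=-2.0, E_sep=-0.5, a=1.5, Z1=1, Z2=1,
                             q_lr=1.0, b=0.5, R_min=0.026, R_max=10.583,
                             n_points=401, symbols=("H", "H"))


def generate_diatomic_table(spec: ModelDiatomicSpec) -> EnergyTable:
    """Exact E_el and V on the spec's R grid (table in internal units)."""
    R_ang = np.linspace(spec.R_min, spec.R_max, spec.n_points)
    R = R_ang * ANGSTROM_TO_BOHR
    eel = spec.electronic_energy(R)
    v = eel + spec.Z1 * spec.Z2 / R
    cs = CoordinateSpec("diatomic_R", spec.atoms())
    return EnergyTable(cs, R.reshape(-1, 1), V=v, Eel=eel,
                       provenance="synthetic diatomic model")


@dataclass
class ModelTriatomicSpec:
    """Sum-of-pairs triatomic model plus a Gaussian three-body term.

    ``pair_specs`` maps the pairs (0,1), (1,2), (0,2) to diatomic models
    (their grids are ignored; only the closed form is used).  The
    three-body term is A * exp(-sum ((x - x0)^2 / 2 sigma^2)) in the
    Jacobi coordinates (R, r, theta), with A in hartree.
    """

    atoms: tuple = ()
    pair_specs: dict = field(default_factory=dict)
    three_body_amplitude: float = 0.0
    three_body_center: tuple = (4.0, 2.0, 90.0)     # (R bohr, r bohr, theta deg)
    three_body_widths: tuple = (1.5, 0.7, 40.0)
    R_range: tuple = (1.0, 10.0)        # angstrom
    r_range: tuple = (0.55, 1.3)        # angstrom
    theta_range: tuple = (0.0, 180.0)   # degrees
    n_R: int = 16
    n_r: int = 6
    n_theta: int = 13
    assignment: str = "A"

    def coordinate_spec(self) -> CoordinateSpec:
        return CoordinateSpec("jacobi_3d", self.atoms,
                              fixed_params={"assignment": self.assignment})

    def electronic_energy(self, R_bohr, r_bohr, theta_deg) -> float:
        masses = (self.atoms[0].mass, self.atoms[1].mass)
        d_ab, d_ca, d_cb = jacobi_to_distances(R_bohr, r_bohr, theta_deg,
                                               masses, self.assignment)
        e = (self.pair_specs[(0, 1)].electronic_energy(d_ab)
             + self.pair_specs[(1, 2)].electronic_energy(d_cb)
             + self.pair_specs[(0, 2)].electronic_energy(d_ca))
        if self.three_body_amplitude:
            x = np.array([R_bohr, r_bohr, theta_deg])
            x0 = np.asarray(self.three_body_center)
            s = np.asarray(self.three_body_widths)
            e += self.three_body_amplitude * math.exp(
                -float(np.sum((x - x0) ** 2 / (2.0 * s ** 2))))
        return float(e)


def he2h_like() -> ModelTriatomicSpec:
    """Preset emulating a helium-hydride-cation + helium Jacobi surface."""
    he = AtomSpec.from_symbol("He")
    h = AtomSpec.from_symbol("H")
    heh = ModelDiatomicSpec(E_ua=-7.28, E_sep=-2.904, a=1.2, Z1=2, Z2=1,
                            q_lr=2.0, b=0.6, symbols=("He", "H"))
    hehe = ModelDiatomicSpec(E_ua=-14.67, E_sep=-5.807, a=1.5, Z1=2, Z2=2,
                             q_lr=0.0, symbols=("He", "He"))
    return ModelTriatomicSpec(
        atoms=(he, h, he),
        pair_specs={(0, 1): heh, (1, 2): heh, (0, 2): hehe},
        three_body_amplitude=0.02,
        three_body_center=(4.0, 1.8, 90.0),
        three_body_widths=(1.5, 0.6, 45.0),
    )


def generate_jacobi_table(spec: ModelTriatomicSpec) -> EnergyTable:
    """Regular (R, r, theta) grid with exact model E_el and V = E_el + V_nu."""
    cs = spec.coordinate_spec()
    R = np.linspace(*spec.R_range, spec.n_R) * ANGSTROM_TO_BOHR
    r = np.linspace(*spec.r_range, spec.n_r) * ANGSTROM_TO_BOHR
    th = np.linspace(*spec.theta_range, spec.n_theta)
    coords = np.array([(Ri, ri, ti) for Ri in R for ri in r for ti in th])
    eel = np.array([spec.electronic_energy(*row) for row in coords])
    vnu = cs.vnu(coords)
    return EnergyTable(cs, coords, V=eel + vnu, Eel=eel,
                       provenance="synthetic Jacobi triatomic model")


def ethane_frame() -> tuple[MolecularFrame, tuple, tuple]:
    """Rigid staggered ethane-like frame (bohr).

    Returns (frame, dihedral_atoms, rotate_atoms) for torsion scans:
    atoms 0-1 are the carbons, 2-4 the front methyl hydrogens and 5-7 the
    rotating back methyl hydrogens.
    """
    r_cc = 1.536 * ANGSTROM_TO_BOHR
    r_ch = 1.091 * ANGSTROM_TO_BOHR
    ang = math.radians(111.2)           # H-C-C angle
    c = AtomSpec.from_symbol("C")
    h = AtomSpec.from_symbol("H")
    z_h = r_ch * math.cos(math.pi - ang)
    rho = r_ch * math.sin(math.pi - ang)
    pos = [[0.0, 0.0, 0.0], [0.0, 0.0, r_cc]]
    for k in range(3):                   # front methyl on atom 0, staggered
        phi = math.radians(120.0 * k)
        pos.append([rho * math.cos(phi), rho * math.sin(phi), z_h])
    for k in range(3):                   # back methyl on atom 1
        phi = math.radians(60.0 + 120.0 * k)
        pos.append([rho * math.cos(phi), rho * math.sin(phi), r_cc - z_h])
    frame = MolecularFrame((c, c, h, h, h, h, h, h), np.asarray(pos))
    return frame, (2, 0, 1, 5), (5, 6, 7)


@dataclass
class TorsionSpec:
    """Fourier torsion model: E_el(phi) = c0 + c3 (1+cos 3phi)/2
    + c6 (1+cos 6phi)/2 (hartree), on a rigid rotating template."""

    c0: float = -79.8
    c3: float = -500.0 / HARTREE_TO_INVCM
    c6: float = -50.0 / HARTREE_TO_INVCM
    phi_min: float = -180.0
    phi_max: float = 180.0
    n_points: int = 61
    template: MolecularFrame = None
    dihedral_atoms: tuple = None
    rotate_atoms: tuple = None

    def electronic_energy(self, phi_deg) -> np.ndarray:
        p = np.radians(np.asarray(phi_deg, dtype=float))
        return (self.c0 + self.c3 * (1.0 + np.cos(3.0 * p)) / 2.0
                + self.c6 * (1.0 + np.cos(6.0 * p)) / 2.0)


def ethane_like() -> TorsionSpec:
    frame, dih, rot = ethane_frame()
    return TorsionSpec(template=frame, dihedral_atoms=dih, rotate_atoms=rot)


def generate_torsion_table(spec: TorsionSpec) -> EnergyTable:
    """Periodic torsion curve; V_nu from the rigid rotated template.

    With the default [-180, 180] grid the first and last records describe
    the same physical conformer (the coordinate values differ, the
    energies agree exactly), mirroring how rigid-scan tables are reported.
    """
    if spec.template is None or spec.dihedral_atoms is None:
        raise ValueError("torsion spec needs a template frame and dihedral atoms")
    cs = CoordinateSpec("torsion", spec.template.atoms,
                        fixed_params={"template": spec.template,
                                      "dihedral_atoms": spec.dihedral_atoms,
                                      "rotate_atoms": spec.rotate_atoms})
    phi = np.linspace(spec.phi_min, spec.phi_max, spec.n_points)
    eel = spec.electronic_energy(phi)
    vnu = cs.vnu(phi.reshape(-1, 1))
    return EnergyTable(cs, phi.reshape(-1, 1), V=eel + vnu, Eel=eel,
                       provenance="synthetic torsion model")


def add_noise(table: EnergyTable, sigma_cm: float, seed: int) -> EnergyTable:
    """Gaussian perturbation of E_el (V updated consistently), seeded.

    ``sigma_cm = 0`` returns an identical table.
    """
    if sigma_cm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_cm == 0:
        return table.copy_with()
    rng = np.random.default_rng(seed)
    noise_h = rng.normal(0.0, sigma_cm, size=len(table)) / HARTREE_TO_INVCM
    eel = table.Eel + noise_h
    v = table.V.copy()
    ok = ~table.is_united_atom & ~np.isnan(v)
    v[ok] = eel[ok] + table.Vnu[ok]
    return table.copy_with(Eel=eel, V=v)
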