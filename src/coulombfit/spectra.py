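"""Vibrational bound states and stationary-point analysis.

The 1-D radial Schrodinger equation is solved on a uniform grid with the
Fourier-grid / sinc-DVR Hamiltonian: the potential is diagonal and the
kinetic operator has the closed-form matrix elements (atomic units)

    T_ii = (1 / 2m) * pi^2 / (3 dx^2)
    T_ij = (1 / 2m) * (2 / dx^2) * (-1)^(i-j) / (i-j)^2,   i != j,

whose eigenvalues converge rapidly with grid density.  Bound states are
the eigenvalues below the dissociation asymptote; convergence is verified
by doubling the grid and requiring retained levels to move by less than
0.01 cm^-1.

Minima and harmonic frequencies on fitted surfaces use finite-difference
derivatives (central differences, one Richardson refinement for the
Hessian) with a diagonal reduced-mass metric supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .constants import (AMU_TO_ME, ANGSTROM_TO_BOHR, HARTREE_TO_INVCM,
                        cm_to_hartree, hartree_to_cm)

__all__ = ["GridSpec", "BoundStateResult", "StationaryPoint",
           "fgh_levels_au", "fgh_bound_states", "find_minimum",
           "harmonic_frequencies", "jacobi_reduced_masses"]

#: retained-level convergence tolerance under grid doubling, cm^-1
FGH_CONVERGENCE_CM = 0.01


@dataclass
class GridSpec:
    """Uniform radial grid in angstrom; must span the well and the
    classically allowed region of the highest sought level."""

    R_min: float
    R_max: float
    n: int = 512

    def __post_init__(self):
        if not self.R_min > 0:
            raise ValueError("R_min must be positive")
        if not self.R_max > self.R_min:
            raise ValueError("R_max must exceed R_min")
        if self.n < 64:
            raise ValueError("need at least 64 grid points")


@dataclass
class BoundStateResult:
    """Bound vibrational levels of a 1-D curve.

    ``energies`` are in cm^-1 relative to the dissociation asymptote
    (negative, strictly increasing); ``mu_amu`` is the reduced mass used.
    """

    energies: np.ndarray
    grid: GridSpec
    mu_amu: float
    asymptote_cm: float

    @property
    def n_bound(self) -> int:
        return len(self.energies)


def _sinc_dvr_hamiltonian(v_diag: np.ndarray, mass: float, dx: float) -> np.ndarray:
    n = len(v_diag)
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    with np.errstate(divide="ignore"):
        T = 2.0 * np.where(diff == 0, 0.0, ((-1.0) ** diff) / (diff ** 2.0))
    np.fill_diagonal(T, math.pi ** 2 / 3.0)
    T *= 1.0 / (2.0 * mass * dx * dx)
    H = T
    H[np.diag_indices(n)] += v_diag
    return H


def fgh_levels_au(potential, mass_me: float, x_min: float, x_max: float,
                  n: int, eigvecs: bool = False):
    """Eigenvalues (hartree) of the 1-D grid Hamiltonian in atomic units.

    ``potential`` maps position (bohr) to energy (hartree); ``mass_me`` is
    the mass in electron masses.  This is the unit-free core used both by
    the bound-state driver and by the closed-form oracle tests.
    """
    if mass_me <= 0:
        raise ValueError("mass must be positive")
    x = np.linspace(x_min, x_max, n)
    v = np.asarray(potential(x), dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("potential is not finite everywhere on the grid")
    H = _sinc_dvr_hamiltonian(v, mass_me, x[1] - x[0])
    if eigvecs:
        w, U = np.linalg.eigh(H)
        return x, w, U
    return x, np.linalg.eigvalsh(H)


def fgh_bound_states(curve, mu_amu: float, grid: GridSpec,
                     asymptote_cm: float,
                     check_convergence: bool = True) -> BoundStateResult:
    """Bound levels of a 1-D potential curve via the grid Hamiltonian.

    ``curve`` maps R (angstrom) to absolute V (cm^-1); ``mu_amu`` is the
    reduced mass in unified amu, and ``asymptote_cm`` the dissociation
    energy on the same absolute scale.  Levels at or above the asymptote
    are discarded.  A diagnostic error is raised if the lowest bound
    eigenfunction has appreciable amplitude at the grid edge (grid too
    small to contain the well).
    """
    if mu_amu <= 0:
        raise ValueError("reduced mass must be positive")
    mass_me = mu_amu * AMU_TO_ME
    a_h = cm_to_hartree(asymptote_cm)

    def pot_au(x_bohr):
        r_ang = np.asarray(x_bohr) / ANGSTROM_TO_BOHR
        return cm_to_hartree(np.asarray(curve(r_ang), dtype=float))

    x_min = grid.R_min * ANGSTROM_TO_BOHR
    x_max = grid.R_max * ANGSTROM_TO_BOHR

    def _levels(n):
        x, w, U = fgh_levels_au(pot_au, mass_me, x_min, x_max, n, eigvecs=True)
        keep = w < a_h
        return w[keep], U[:, keep]

    w, U = _levels(grid.n)
    if len(w):
        psi0 = U[:, 0]
        edge = max(abs(psi0[0]), abs(psi0[-1])) / np.max(np.abs(psi0))
        if edge > 1e-4:
            raise ValueError(
                "grid too small: the lowest eigenfunction has relative edge "
                f"amplitude {edge:.2g}; widen [R_min, R_max]")
    if check_convergence and len(w):
        w2, _ = _levels(2 * grid.n - 1)
        if len(w2) != len(w):
            raise ValueError(
                f"bound-state count not converged: {len(w)} at n={grid.n} vs "
                f"{len(w2)} at doubled resolution; increase n")
        dev = np.max(np.abs(hartree_to_cm(w - w2)))
        if dev > FGH_CONVERGENCE_CM:
            raise ValueError(
                f"levels not converged: doubling the grid moves them by "
                f"{dev:.3g} cm^-1 (> {FGH_CONVERGENCE_CM}); increase n")
        w = w2
    energies = hartree_to_cm(np.sort(w) - a_h)
    return BoundStateResult(energies=np.asarray(energies), grid=grid,
                            mu_amu=mu_amu, asymptote_cm=asymptote_cm)


@dataclass
class StationaryPoint:
    coordinates: np.ndarray
    energy: float                 # same units as the surface (cm^-1)
    gradient_norm: float
    hessian: np.ndarray | None = None
    hessian_eigenvalues: np.ndarray | None = None
    frequencies_cm: np.ndarray | None = None
    extrapolated: bool = False


def _fd_gradient(f, x, h):
    g = np.empty(len(x))
    for k in range(len(x)):
        e = np.zeros(len(x))
        e[k] = h[k]
        g[k] = (f(x + e) - f(x - e)) / (2.0 * h[k])
    return g


def _fd_hessian(f, x, h):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _richardson_hessian(f, x, h):
    # H(h) has O(h^2) error; one Richardson step: (4 H(h/2) - H(h)) / 3
    return (4.0 * _fd_hessian(f, x, h / 2.0) - _fd_hessian(f, x, h)) / 3.0


def find_minimum(surface, x0, bounds=None, grad_tol: float = 1e-8,
                 hull=None, step: float = 1e-3) -> StationaryPoint:
    """Locate a local minimum of a scalar surface by quasi-Newton descent.

    ``surface`` maps a coordinate vector (native units) to energy; the
    finite-difference gradient norm at the solution must fall below
    ``grad_tol`` (in energy per native unit).  ``hull`` may give
    (lower, upper) coordinate bounds of the fitted data; a minimiser
    outside them is flagged ``extrapolated``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    h = np.full(len(x0), step)

    def f(x):
        return float(np.asarray(surface(x)).ravel()[0])

    res = scipy.optimize.minimize(f, x0, method="Nelder-Mead",
                                  options=dict(xatol=1e-12, fatol=1e-14,
                                               maxiter=20000, maxfev=40000))
    res2 = scipy.optimize.minimize(f, res.x, method="Powell", bounds=bounds,
                                   options=dict(xtol=1e-12, ftol=1e-15))
    x = res2.x if res2.fun <= res.fun else res.x
    g = _fd_gradient(f, x, h * 1e-2)
    gnorm = float(np.linalg.norm(g))
    H = _richardson_hessian(f, x, h)
    evals = np.linalg.eigvalsh(H)
    extrap = False
    if hull is not None:
        lo, hi = (np.asarray(b, float) for b in hull)
        extrap = bool(np.any(x < lo) or np.any(x > hi))
    if gnorm > grad_tol:
        raise RuntimeError(
            f"minimisation did not converge: |grad| = {gnorm:.3g} > {grad_tol}")
    return StationaryPoint(coordinates=x, energy=f(x), gradient_norm=gnorm,
                           hessian=H, hessian_eigenvalues=evals,
                           extrapolated=extrap)


def harmonic_frequencies(surface, point, masses_amu, coord_units,
                         step: float = 1e-3) -> np.ndarray:
    """Harmonic frequencies (cm^-1) at a stationary point.

    ``surface`` maps coordinates (native units) to energy in cm^-1;
    ``masses_amu`` gives the reduced mass conjugate to each coordinate,
    and ``coord_units`` the native length unit per coordinate
    ("angstrom" or "bohr") so the Hessian can be expressed in atomic
    units.  The mass-weighted Hessian is diagonalised; a negative
    curvature yields an imaginary frequency reported as negative.
    """
    x = np.atleast_1d(np.asarray(point, dtype=float))
    masses = np.atleast_1d(np.asarray(masses_amu, dtype=float))
    units = [coord_units] * len(x) if isinstance(coord_units, str) else list(coord_units)
    scale = []
    for u in units:
        if u == "angstrom":
            scale.append(ANGSTROM_TO_BOHR)
        elif u == "bohr":
            scale.append(1.0)
        else:
            raise ValueError(f"unsupported coordinate unit {u!r} for frequencies")
    scale = np.asarray(scale)

    def f(xx):
        return float(np.asarray(surface(xx)).ravel()[0])

    H = _richardson_hessian(f, x, np.full(len(x), step))
    # cm^-1 / native^2  ->  hartree / bohr^2
    H_au = H / HARTREE_TO_INVCM / np.outer(scale, scale)
    m_me = masses * AMU_TO_ME
    Hmw = H_au / np.sqrt(np.outer(m_me, m_me))
    lam = np.linalg.eigvalsh(Hmw)     # omega^2 in atomic units
    freq = np.sign(lam) * np.sqrt(np.abs(lam)) * HARTREE_TO_INVCM
    return np.sort(freq)


def jacobi_reduced_masses(m_a: float, m_b: float, m_c: float) -> tuple[float, float]:
    """Reduced masses (amu) conjugate to the Jacobi stretches (R, r).

    r couples the diatom A-B; R couples the projectile C against the
    diatom's total mass.
    """
    mu_r = m_a * m_b / (m_a + m_b)
    mu_R = m_c * (m_a + m_b) / (m_a + m_b + m_c)
    return mu_R, mu_r
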