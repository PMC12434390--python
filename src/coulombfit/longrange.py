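"""Long-range extension of fitted 1-D potential curves.

A fitted network represents the curve only inside its data range; bound
states near dissociation also sample the long-range tail.  The extension
appends an analytic inverse-power tail

    V_tail(R) = asymptote - sum_n C_n / R^n      (C_n in atomic units)

smoothly connected to the fit through a half-cosine switching function:
s(R) = 1 below R1, 0 above R2, and 1/2 * (1 + cos(pi (R-R1)/(R2-R1)))
in between, which is monotone and C^1.  The blended curve is
s * V_fit + (1-s) * V_tail.

Presets are provided for the leading ion-induced-dipole (-C4/R^4) and
dispersion (-C6/R^6) terms; coefficients are user inputs.  Lengths here
are in angstrom and energies in cm^-1 (the package's I/O units); tail
coefficients C_n are in atomic units as is conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, HARTREE_TO_INVCM

__all__ = ["TailForm", "SwitchWindow", "ExtendedCurve",
           "switch_value", "evaluate_extended", "ion_induced_dipole_tail",
           "dispersion_tail"]


@dataclass
class TailForm:
    """Analytic long-range form: asymptote - sum_n C_n / R^n.

    ``inverse_power_terms`` is a list of ``(n, C_n)`` with C_n in atomic
    units (hartree * bohr^n); ``asymptote`` is the dissociation energy in
    cm^-1 on the same absolute scale as the fitted curve.
    """

    inverse_power_terms: list = field(default_factory=list)
    asymptote: float = 0.0  # cm^-1

    def __post_init__(self):
        for n, _c in self.inverse_power_terms:
            if n < 1:
                raise ValueError(f"inverse power n must be >= 1, got {n}")

    def __call__(self, R_angstrom) -> np.ndarray:
        """Tail energy (cm^-1) at R (angstrom)."""
        R_b = np.asarray(R_angstrom, dtype=float) * ANGSTROM_TO_BOHR
        v = np.zeros_like(R_b)
        for n, c in self.inverse_power_terms:
            v -= c / R_b ** n
        return self.asymptote + v * HARTREE_TO_INVCM


def ion_induced_dipole_tail(polarizability_au: float, charge: float = 1.0,
                            asymptote: float = 0.0) -> TailForm:
    """Leading charge-induced-dipole tail -alpha q^2 / (2 R^4)."""
    return TailForm([(4, 0.5 * polarizability_au * charge ** 2)], asymptote)


def dispersion_tail(C6_au: float, asymptote: float = 0.0) -> TailForm:
    """Leading dispersion tail -C6 / R^6."""
    return TailForm([(6, C6_au)], asymptote)


@dataclass
class SwitchWindow:
    """Blend window: pure fit below R1, pure tail above R2 (angstrom)."""

    R1: float
    R2: float

    def __post_init__(self):
        if not self.R1 < self.R2:
            raise ValueError(f"switch window requires R1 < R2, got "
                             f"({self.R1}, {self.R2})")


def switch_value(R, window: SwitchWindow) -> np.ndarray:
    """Half-cosine switching weight in [0, 1]; 1 below R1, 0 above R2.

    Monotone and C^1: the derivative vanishes at both window edges.
    """
    R = np.asarray(R, dtype=float)
    t = np.clip((R - window.R1) / (window.R2 - window.R1), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def default_window(train_R_angstrom) -> SwitchWindow:
    """Default blend window: 90th percentile of the training R to its max."""
    r = np.asarray(train_R_angstrom, dtype=float)
    return SwitchWindow(float(np.percentile(r, 90.0)), float(r.max()))


@dataclass
class ExtendedCurve:
    """A fitted 1-D curve blended into an analytic tail.

    ``fitted`` is a callable R (angstrom) -> V (cm^-1); use
    :meth:`from_fitted_pes` to wrap a 1-D :class:`~coulombfit.schemes.FittedPES`
    (whose native length unit is bohr).
    """

    fitted: object          # callable, angstrom -> cm^-1
    tail: TailForm
    window: SwitchWindow

    def __call__(self, R_angstrom):
        return evaluate_extended(self, R_angstrom)

    @classmethod
    def from_fitted_pes(cls, pes, tail: TailForm,
                        window: SwitchWindow) -> "ExtendedCurve":
        curve_bohr = pes.potential_curve()

        def fitted(R_angstrom):
            return curve_bohr(np.asarray(R_angstrom, float) * ANGSTROM_TO_BOHR)

        return cls(fitted=fitted, tail=tail, window=window)


def evaluate_extended(curve: ExtendedCurve, R_angstrom) -> np.ndarray:
    """Blended potential s*V_fit + (1-s)*V_tail, in cm^-1.

    Below R1 this is exactly the fitted curve; above R2 exactly the tail,
    which approaches the declared asymptote as R -> infinity.
    """
    R = np.atleast_1d(np.asarray(R_angstrom, dtype=float))
    if np.any(R <= 0):
        raise ValueError("R must be positive")
    s = switch_value(R, curve.window)
    v = np.empty_like(R)
    lo = s > 0.0
    hi = s < 1.0
    v[:] = 0.0
    if np.any(lo):
        v[lo] += s[lo] * np.asarray(curve.fitted(R[lo]), float).ravel()
    if np.any(hi):
        v[hi] += (1.0 - s[hi]) * curve.tail(R[hi])
    return v if np.ndim(R_angstrom) else float(v[0])
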