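"""Physical constants and unit conversions (CODATA 2018).

All internal arithmetic in this package is done in Hartree atomic units
(energy in hartree, length in bohr, mass in electron masses); wavenumbers,
angstroms and unified amu appear only at I/O boundaries.
"""

#: 1 hartree expressed in wavenumbers (cm^-1).
HARTREE_TO_INVCM: float = 219474.6313632

#: 1 angstrom expressed in bohr.
ANGSTROM_TO_BOHR: float = 1.0 / 0.529177210903

#: 1 bohr expressed in angstrom.
BOHR_TO_ANGSTROM: float = 0.529177210903

#: 1 unified atomic mass unit expressed in electron masses.
AMU_TO_ME: float = 1822.888486209

#: Proton mass in unified amu (nuclear mass of 1H, electron stripped).
PROTON_MASS_AMU: float = 1.007276466621

#: Alpha-particle mass in unified amu (nuclear mass of 4He).
ALPHA_MASS_AMU: float = 4.001506179127


def cm_to_hartree(e_cm):
    """Convert an energy from cm^-1 to hartree."""
    return e_cm / HARTREE_TO_INVCM


def hartree_to_cm(e_h):
    """Convert an energy from hartree to cm^-1."""
    return e_h * HARTREE_TO_INVCM


def angstrom_to_bohr(r_a):
    """Convert a length from angstrom to bohr."""
    return r_a * ANGSTROM_TO_BOHR


def bohr_to_angstrom(r_b):
    """Convert a length from bohr to angstrom."""
    return r_b * BOHR_TO_ANGSTROM
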