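"""Unit conversion constants (CODATA 2018).

Internal computations use Hartree atomic units (hartree, bohr, hbar = 1).
User-facing I/O uses angstrom for lengths, femtoseconds/attoseconds for
times and cm^-1 for frequencies; every conversion goes through this table.
"""

#: atomic units of time per femtosecond
AU_TIME_PER_FS = 41.341374575751

#: angstrom per bohr radius
ANGSTROM_PER_BOHR = 0.529177210903
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

#: wavenumbers (cm^-1) per hartree
CM1_PER_HARTREE = 219474.6313632

#: Debye per atomic unit of electric dipole (e * bohr)
DEBYE_PER_E_BOHR = 2.541746473

#: speed of light in cm per femtosecond (2.99792458e10 cm/s)
SPEED_OF_LIGHT_CM_PER_FS = 2.99792458e-5

_TIME_UNITS_TO_FS = {"fs": 1.0, "as": 1e-3, "ps": 1e3}


def time_to_fs(value: float, unit: str) -> float:
    """Convert a time given in ``fs``, ``as`` or ``ps`` to femtoseconds."""
    try:
        return value * _TIME_UNITS_TO_FS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(_TIME_UNITS_TO_FS)}"
        ) from None
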