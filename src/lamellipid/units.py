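"""Unit conventions and converters.

Internal units are nm (length), ps (time), amu (mass), kJ/mol (energy).
Converters live here; nothing outside I/O boundaries should convert.
"""

#: Gas constant in kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314462618e-3

#: amu expressed in kg.
AMU_KG = 1.66053906660e-27

#: Standard atomic masses (amu) for the elements the generator emits.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "NA": 22.990,
    "Na": 22.990,
}

#: Residue names recognised as water by default.
WATER_RESNAMES = ("SOL", "HOH", "TIP3", "WAT")


def nm2_per_ps_to_cm2_per_s(d: float) -> float:
    """1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s."""
    return d * 1e-2


def cm2_per_s_to_nm2_per_ps(d: float) -> float:
    return d * 1e2


def nm2_per_ps_to_nm2_per_ns(d: float) -> float:
    return d * 1e3


def celsius_to_kelvin(t: float) -> float:
    return t + 273.15


def angstrom_to_nm(x):
    return x * 0.1


def nm_to_angstrom(x):
    return x * 10.0
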