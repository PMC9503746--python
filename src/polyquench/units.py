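"""Unit conventions and physical constants.

Energies are carried internally in units of k_B·kelvin (k_B = 1), so an
activation energy "Δa = 1.2e4 K" means Δa/k_B = 1.2e4 kelvin.  Conversions to
laboratory units happen only at interfaces.
"""

#: Seconds per year used for dwell-time reporting.
SECONDS_PER_YEAR = 3.156e7

#: kelvin of (E/k_B) per kcal/mol, for activation energies quoted in kcal/mol.
KELVIN_PER_KCAL_PER_MOL = 503.2

#: Avogadro's number, 1/mol.
AVOGADRO = 6.022e23


def years_to_seconds(t_years: float) -> float:
    return t_years * SECONDS_PER_YEAR


def seconds_to_years(t_seconds: float) -> float:
    return t_seconds / SECONDS_PER_YEAR


def kcal_per_mol_to_kelvin(e_kcal: float) -> float:
    return e_kcal * KELVIN_PER_KCAL_PER_MOL
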