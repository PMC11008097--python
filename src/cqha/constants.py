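"""Physical constants and unit conversions.

Internal units are fixed throughout the package: volumes in Å³ per unit
cell, energies in kJ mol⁻¹ per unit cell, frequencies in THz, temperatures
in K, pressures in GPa.  Conversions happen only at I/O boundaries.

Values are CODATA 2018 (exact where the SI defines them).
"""

from __future__ import annotations

#: Avogadro constant, mol⁻¹ (exact).
N_A = 6.02214076e23
#: Planck constant, J s (exact).
H_PLANCK = 6.62607015e-34
#: Boltzmann constant, J K⁻¹ (exact).
K_B = 1.380649e-23
#: Molar gas constant, J K⁻¹ mol⁻¹ (exact, = N_A · k_B).
R_GAS = N_A * K_B

#: 1 GPa·Å³ expressed in kJ mol⁻¹ (per particle count of one mole).
#: 1 GPa·Å³ = 1e9 Pa · 1e-30 m³ = 1e-21 J; × N_A / 1000 → kJ mol⁻¹.
GPA_A3_TO_KJMOL = 1.0e-21 * N_A / 1000.0

#: h·ν/k_B for ν in THz: characteristic temperature per THz, K.
THZ_TO_K = H_PLANCK * 1.0e12 / K_B

#: N_A·h·ν for ν in THz, in kJ mol⁻¹ (molar energy of one quantum).
THZ_TO_KJMOL = N_A * H_PLANCK * 1.0e12 / 1000.0

#: Energy-unit conversion factors into kJ mol⁻¹.
ENERGY_TO_KJMOL = {
    "kj/mol": 1.0,
    "kjmol": 1.0,
    "ev": 96.48533212331002,       # e·N_A/1000 with e = 1.602176634e-19 C
    "hartree": 2625.4996394798254,  # 2 Ry in kJ/mol, CODATA 2018
    "kcal/mol": 4.184,
    "kcalmol": 4.184,
}


def energy_factor(unit: str) -> float:
    """Return the multiplicative factor converting *unit* to kJ mol⁻¹."""
    key = unit.strip().lower()
    if key not in ENERGY_TO_KJMOL:
        raise ValueError(
            f"unknown energy unit {unit!r}; known: {sorted(ENERGY_TO_KJMOL)}"
        )
    return ENERGY_TO_KJMOL[key]
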