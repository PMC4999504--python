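"""Physical constants and unit conventions.

The package works in a single fixed unit system throughout:
length Å, time ps, mass amu, temperature K, energy kcal/mol,
wavenumber cm⁻¹, mass density g/cc.
"""

# Boltzmann constant, kcal/mol/K
KB_KCAL = 0.0019872041

# 1 amu in grams
AMU_TO_G = 1.66053906660e-24

# speed of light in cm/ps (converts ps⁻¹ frequency axes to cm⁻¹)
C_CM_PER_PS = 0.0299792458

# 1 Å³ in cc
A3_TO_CC = 1.0e-24

# molar mass of water, amu
WATER_MASS_AMU = 18.0154

#: default atomic masses (amu) used when building topologies from files
ELEMENT_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    # coarse-grained bead pseudo-element (MARTINI-scale 72 amu)
    "B": 72.0,
}


def element_mass(element: str) -> float:
    """Mass in amu for an element symbol; unknown symbols get 12.011 (C)."""
    return ELEMENT_MASSES.get(element.strip().upper(), 12.011)


def mass_density_g_cc(total_mass_amu: float, volume_a3: float) -> float:
    """Convert a mass in amu inside a volume in Å³ to g/cc."""
    return total_mass_amu * AMU_TO_G / (volume_a3 * A3_TO_CC)
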