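"""Physical constants and unit conventions.

Internal units throughout the package: length mm, time h, amount mmol,
biomass g_DW.  Concentrations are mM (mmol/L); 1 mm^3 = 1e-6 L, so a
concentration in mM equals (amount in mmol) * 1e6 / (volume in mm^3).
Diffusion coefficients are configured in mm^2/ms (the unit experimental
tables use) and converted once to mm^2/h at load time.
"""

AVOGADRO = 6.02214076e23  # molecules per mol

#: conversion factor mm^3 -> L appearing in effective-concentration formulas
MM3_PER_L = 1e-6
L_PER_MM3 = 1e6  # multiply mmol/mm^3 by this to get mM

#: mol -> mmol factor used in the crowding moments (amounts are in mmol)
MOL_PER_MMOL = 1e-3

MS_PER_H = 3.6e6


def d0_to_internal(d0_mm2_per_ms: float) -> float:
    """Convert a diffusion coefficient from mm^2/ms to mm^2/h."""
    return d0_mm2_per_ms * MS_PER_H
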