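"""Physical constants and unit conventions.

Internal unit system: length in Angstrom, mass in amu (g/mol), energy in
kcal/mol, charge in elementary charges, temperature in Kelvin.  The derived
time unit is t0 = sqrt(amu * A^2 / (kcal/mol)) = 48.888 fs, which fixes the
value of hbar below.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 1.9872e-3

#: Reduced Planck constant in internal units, (kcal/mol) * t0.
HBAR = 0.3104783

#: Coulomb conversion factor, kcal A / (mol e^2).
COULOMB_K = 332.0636

#: Solvent (outer) dielectric for the continuum reaction-field term.
SOLVENT_DIELECTRIC = 78.5

#: Water probe radius for surface-area estimation, Angstrom.
PROBE_RADIUS = 1.4

#: Simulation temperature of the source trajectories, K.
DEFAULT_TEMPERATURE = 310.0

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

#: Backbone heavy/polar-H atom names (everything else is side chain).
BACKBONE_ATOMS = frozenset({"N", "H", "CA", "HA", "C", "O", "OXT"})
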