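"""Physical constants and package-wide defaults.

All free energies are in kcal/mol, concentrations in molar (standard state
1 M is implicit in every ``RT ln Kd`` expression), distances in Angstrom,
charges in elementary charge units, and temperatures in Kelvin.
"""

#: Gas constant, kcal / (mol K).
R_KCAL = 1.98720425e-3

#: Default temperature (K) for free-energy conversions.
DEFAULT_TEMPERATURE = 300.0

#: Coulomb prefactor, kcal * Angstrom / (mol * e^2)  (CHARMM convention).
COULOMB_CONSTANT = 332.0636

#: Nonpolar solvation surface-tension coefficient, kcal / (mol * Angstrom^2).
NONPOLAR_GAMMA = 0.0072

#: Water probe radius for solvent-accessible surface area, Angstrom.
DEFAULT_PROBE_RADIUS = 1.4
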