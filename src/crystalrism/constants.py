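"""Project-wide physical constants and unit conventions.

Internal units everywhere: length in Å, energy in kcal/mol, charge in units
of the elementary charge e, temperature in K.  Lennard-Jones parameters are
stored Amber-style as (epsilon, r_min/2); sigma inputs are converted on read.
"""

#: Coulomb conversion constant, kcal·Å/(mol·e²) — Amber convention.
COULOMB = 332.0522173

#: Boltzmann constant, kcal/(mol·K).
KBOLTZ = 1.987204259e-3

#: Madelung constant of the cubic Wigner lattice (point charge + uniform
#: neutralizing background).  ``thermo.wigner_constant`` recomputes this from
#: scratch; the module constant is for quick reference only.
WIGNER_ZETA = 2.8372974794806

#: sigma -> r_min conversion for 12-6 LJ: r_min = 2^(1/6) sigma.
SIGMA_TO_RMIN = 2.0 ** (1.0 / 6.0)
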