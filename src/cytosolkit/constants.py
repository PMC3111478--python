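"""Physical constants and unit conversions.

Internal unit system: Å (length), ps (time), elementary charge e (charge),
kelvin (temperature).  All reported quantities are converted at the output
boundary:

* diffusion coefficients: Å²/ps and 10⁻⁵ cm²/s  (1 Å²/ps = 10 × 10⁻⁵ cm²/s)
* conductivity: S/m
* dielectric constants: dimensionless, in units of the vacuum permittivity ε0
"""

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

ANGSTROM = 1e-10  # m
PICOSECOND = 1e-12  # s

# 1 Å²/ps expressed in units of 1e-5 cm²/s (the conventional reporting
# unit for small-molecule diffusion coefficients).
# 1 Å²/ps = 1e-8 m²/s = 1e-4 cm²/s = 10 × 1e-5 cm²/s
D_A2_PER_PS_TO_1E5_CM2_PER_S = (ANGSTROM**2 / PICOSECOND) * 1e4 / 1e-5

# Dimensionless prefactor K for dielectric fluctuation terms:
#   eps_term = K * var(M) [e²Å²] / (3 V[Å³] T[K])
# where K = e² / (ε0 · Å · k_B)  (units: kelvin).
EPS_FLUCT_PREFACTOR = ELEMENTARY_CHARGE**2 / (
    VACUUM_PERMITTIVITY * ANGSTROM * BOLTZMANN
)

# Conversion for conductivity:
#   σ[S/m] = SIGMA_PREFACTOR * s[e²Å²/ps] / (6 V[Å³] T[K])
# with SIGMA_PREFACTOR = e²·(Å²/ps) / (Å³·k_B) in SI → C²·m⁻¹·s⁻¹·J⁻¹·K.
SIGMA_PREFACTOR = (
    ELEMENTARY_CHARGE**2 * (ANGSTROM**2 / PICOSECOND) / (ANGSTROM**3 * BOLTZMANN)
)
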