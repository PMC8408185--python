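"""Physical constants and package-wide defaults.

Units follow the conventions of solution NMR and nucleic-acid
thermodynamics: energies in kcal/mol, rates in s^-1 (first order) or
M^-1 s^-1 (bimolecular), temperatures in Kelvin, chemical shifts in
ppm, RF field amplitudes and offsets in Hz.
"""

# Gas constant in kcal/mol/K.
R_KCAL = 1.9872e-3

# Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor).
KB_OVER_H = 1.380649e-23 / 6.62607015e-34

# Frequency ratios Xi = nu(X)/nu(1H) used to derive Larmor frequencies
# from the proton field (IUPAC recommended values, magnitude only).
GAMMA_RATIOS = {
    "1H": 1.0,
    "13C": 0.25145020,
    "15N": 0.10136767,
}

# Default spectrometer proton frequency (MHz).
DEFAULT_PROTON_FIELD_MHZ = 600.0

# Mismatch-like kinetic penalties of the syn methylamino isomer used by
# the duplex predictor: annealing through the syn pathway is 20-fold
# slower than the unmethylated strand, and the singly H-bonded syn
# duplex melts 80-fold faster.
SYN_KON_PENALTY = 20.0
SYN_KOFF_ACCELERATION = 80.0

# Assumed thermodynamic destabilization of a duplex by a single central
# m6A (kcal/mol), applied in genome-scale prediction tables.
DEFAULT_DDG_M6A = 1.0

# Populations below this are treated as exactly zero to keep stationary
# solves well conditioned.
POPULATION_FLOOR = 1e-12

# B1 inhomogeneity averaging: discrete Gaussian over the RF amplitude.
DEFAULT_B1_SIGMA = 0.10
B1_GRID_POINTS = 11
B1_GRID_SPAN_SIGMA = 2.5
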