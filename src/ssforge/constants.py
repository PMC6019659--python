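"""Ideal stereochemistry and scoring constants, pinned in one place.

Bond lengths/angles are standard protein stereochemistry dictionary values
(Engh & Huber class); the Cβ improper torsion reproduces L-chirality under
the IUPAC dihedral sign convention.
"""

# --- backbone ideal internal coordinates (Å, degrees) ---
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

# --- side-chain virtual mutation (cysteine) ---
BOND_CA_CB = 1.53
ANGLE_N_CA_CB = 110.5
# improper torsion C-N-CA-CB fixing L-chirality of the placed Cβ
TORSION_C_N_CA_CB = -122.6
BOND_CB_SG = 1.81
ANGLE_CA_CB_SG = 114.0
# covalent S-S bond and its bond angle in cystine
BOND_SG_SG = 2.05
ANGLE_CB_SG_SG = 104.0

# default chi1 rotamer seeds for virtual cysteine modelling (degrees)
DEFAULT_ROTAMERS = (-60.0, 60.0, 180.0)

# Sγ-Sγ cutoff for calling a native disulfide (covalent ~2.05 Å + margin)
NATIVE_SG_CUTOFF = 2.3

# the six atoms whose 36 cross-residue distances form the distance block
PAIR_ATOMS = ("C", "O", "N", "CA", "CB", "SG")

# the three corresponding backbone/side-chain planes compared across residues
PLANE_TRIPLES = (("C", "CA", "CB"), ("CA", "CB", "N"), ("C", "CA", "N"))

# histogram binning for the disulfide library
DISTANCE_BIN_WIDTH = 0.25   # Å, over [0, 15]
DISTANCE_RANGE = (0.0, 15.0)
ANGLE_BIN_WIDTH = 10.0      # degrees, over (-180, 180]
ANGLE_RANGE = (-180.0, 180.0)

# loop-closure entropy (Pace form): dS = -2.1 - (3/2) R ln n, cal/mol/K
LOOP_ENTROPY_CONST = -2.1
GAS_CONSTANT_CAL = 1.987          # cal mol^-1 K^-1
ENTROPY_CAP = 25.0                # saturation for mapping |dS| to [0, 1]

# Gaussian width for mapping template RMSD to a probability (Å)
DEFAULT_RMSD_SIGMA = 0.5

# atomic masses (amu) by element for ensemble analysis
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
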