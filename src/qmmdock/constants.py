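"""Global unit conventions and default parameters.

Units are fixed package-wide: lengths in Angstrom, energies in
kcal/mol, charges in elementary charges.
"""

# Coulomb constant in kcal*A/mol/e^2 (CHARMM convention).
COULOMB_KCAL = 332.0637

# Solvation surrogate defaults.
DIELECTRIC_SOLUTE = 2.0
DIELECTRIC_SOLVENT = 78.5
SURFACE_TENSION = 0.015  # kcal/mol/A^2
PROBE_RADIUS = 1.4  # A
MIN_BORN_RADIUS = 1.0  # A

# Nonbonded interactions.
NB_CUTOFF = 12.0  # A

# Boundary treatment.
LINK_LENGTH = 1.10  # A, standard C-H
METAL_CUTOFF = 5.0  # A, metal counted as ligand-bound below this
COORDINATION_CUTOFF = 2.8  # A, first-shell metal coordination
EMBEDDING_SCALE = 0.5  # point charges halved for the embedding field

# Evaluation.
RMSD_SUCCESS_CUTOFF = 1.5  # A, inclusive
CLUSTER_RADIUS = 2.0  # A, symmetry-adapted RMSD

# Optimization.
DEFAULT_CONV = 0.05  # kcal/mol energy convergence
DEFAULT_MAX_STEPS = 200

METAL_ELEMENTS = frozenset(
    {"ZN", "FE", "MG", "CA", "MN", "CU", "NI", "CO", "NA", "K", "CD", "HG"}
)
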