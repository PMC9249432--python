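"""Model constants: the single audited source for every geometry and
potential parameter the interaction model is built from.

Reduced units throughout: energies in units of the thermal energy k_B*T,
lengths in units of the cargo diameter r* (the circumradius of the
pentagonal shell subunit), which maps to roughly 13 nm for carboxysomes.

The published model prints only the interaction well depths; the remaining
geometry (attractor layout, Top/Bottom heights, Morse range) is fixed here
and calibrated so that the configurational-integral binding free energies
reproduce the reference thermodynamic table (hexamer dimerization free
energy g_hh, per-subunit shell free energy, shell-cargo free energy).  See
docs/methods.md for the calibration protocol and rationale.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Site (pseudoatom) type codes.  Attractor classes are registry-specific so
# that an edge-edge contact binds in exactly one registry: the left/mid/right
# attractors of one edge pair only with the right/mid/left attractors of the
# partner edge.
# ---------------------------------------------------------------------------
ATT_PL, ATT_PM, ATT_PR = 0, 1, 2          # pentamer edge (left, mid, right)
ATT_HL, ATT_HM, ATT_HR = 3, 4, 5          # hexamer pentamer-facing edge
ATT_GL2, ATT_GL1, ATT_GR1, ATT_GR2 = 6, 7, 8, 9   # hexamer hexamer-facing edge
# Top/Bottom pseudoatoms come in two flavors.  Edge Tops/Bottoms sit just
# inside each edge midpoint at z = +/- h: their cross-subunit WCA repulsions
# select the preferred dihedral angle (Top-Top engages when a bonded contact
# flattens, Bottom-Bottom when it over-bends).  Axial Tops/Bottoms sit on
# the symmetry axis at z = +/- h: they provide central subunit-subunit
# excluded volume, and the hexamer axial Bottom is the cargo-binding site.
TYPE_TP_E, TYPE_TH_E = 10, 11             # edge Tops (pentamer, hexamer)
TYPE_BP_E, TYPE_BH_E = 12, 13             # edge Bottoms
TYPE_TP_A, TYPE_TH_A = 14, 15             # axial Tops
TYPE_BP_A, TYPE_BH_A = 16, 17             # axial Bottoms
TYPE_EXC = 18                             # Excluder (cargo excluded volume)
TYPE_CARGO_R, TYPE_CARGO_G = 19, 20
N_TYPES = 21

ATTRACTOR_TYPES = tuple(range(10))
TOP_TYPES = (TYPE_TP_E, TYPE_TH_E, TYPE_TP_A, TYPE_TH_A)
BOTTOM_TYPES = (TYPE_BP_E, TYPE_BH_E, TYPE_BP_A, TYPE_BH_A)
ATTRACTOR_CLASS_NAMES = {
    ATT_PL: "P_L", ATT_PM: "P_M", ATT_PR: "P_R",
    ATT_HL: "H_L", ATT_HM: "H_M", ATT_HR: "H_R",
    ATT_GL2: "G_L2", ATT_GL1: "G_L1", ATT_GR1: "G_R1", ATT_GR2: "G_R2",
}

# Complementary attractor classes (symmetric).  Pentamer edges pair with the
# hexamer pentamer-facing edges in reversed registry; hexamer-facing edges
# are mutually complementary in reversed registry.  All other attractor
# pairs do not interact.
COMPLEMENTARY_PAIRS = (
    (ATT_PL, ATT_HR), (ATT_PM, ATT_HM), (ATT_PR, ATT_HL),
    (ATT_GL1, ATT_GR1), (ATT_GL2, ATT_GR2),
)

# ---------------------------------------------------------------------------
# Subunit geometry (lengths in r*)
# ---------------------------------------------------------------------------
PENTAMER_CIRCUMRADIUS = 1.0
EDGE_LENGTH = 2.0 * PENTAMER_CIRCUMRADIUS * np.sin(np.pi / 5.0)  # 1.1755705
# A regular hexagon with the same edge length has circumradius == edge length,
# so pentamer and hexamer edges are commensurate on the truncated icosahedron.
HEXAMER_CIRCUMRADIUS = EDGE_LENGTH

# Height of the Top/Bottom pseudoatoms above/below the attractor plane.
TB_HEIGHT = 0.5
# In-plane distance of the edge Tops/Bottoms from their edge midpoint
# (toward the subunit center).  Small insets give a strong angular lever:
# the cross-edge Top-Top distance shrinks rapidly as the contact flattens
# (and Bottom-Bottom as it over-bends), making the preferred curvature stiff.
EDGE_TOP_INSET = 0.15
EDGE_BOTTOM_INSET = 0.5

# Attractor positions along each edge, as fractions of the edge vector.
# Pentamer-hexamer contacts carry 3 Morse bonds, hexamer-hexamer contacts 4;
# these multiplicities are fixed by the slopes of the reference free-energy
# table with respect to the shell-shell well depth (docs/methods.md).
ATT_FRAC_PENT_EDGE = (0.25, 0.50, 0.75)
ATT_FRAC_HEX_EDGE = (0.125, 0.375, 0.625, 0.875)

# ---------------------------------------------------------------------------
# Shell-shell attraction (Morse between complementary attractors)
# ---------------------------------------------------------------------------
# req = 0: complementary attractors coincide in the assembled shell, so the
# ideal blueprint is an exact minimum of every Morse bond (the printed model
# leaves req unstated; this is an assumption, flagged).
MORSE_REQ_SS = 0.0
# Inverse range of the attractor Morse potential.  Calibrated against the
# reference dimerization free energies g_hh(eps_SS = 2.0) = +4 kT and
# g_hh(3.5) = -0.5 kT, which demand a tight attractive basin (interaction
# range ~ 3/alpha = 0.15 r*); see docs/methods.md.
MORSE_ALPHA_SS = 22.0
MORSE_RCUT_SS = 0.35

# ---------------------------------------------------------------------------
# Subunit-subunit repulsions (WCA between Top/Top, Bottom/Bottom, Top/Bottom)
# ---------------------------------------------------------------------------
EPS_REP = 1.0
# Half-width (radians) of the free hinge window around the ideal dihedral
# angle of each bonded edge: the Top-Top and Bottom-Bottom WCA diameters are
# derived from the blueprint so that neither repulsion engages within
# +/- HINGE_HALF_WINDOW of hinge rotation about a bonded edge.  The Top-Top
# diameter exceeds the Bottom-Bottom one, encoding spontaneous curvature.
HINGE_HALF_WINDOW = 0.15

# ---------------------------------------------------------------------------
# Shell-cargo interactions
# ---------------------------------------------------------------------------
# Morse between hexamer Bottom ("B") pseudoatoms and cargo, identical for
# both cargo species.  The rest length is the cargo radius (cargo touching
# the binding site); the range is calibrated so the shell-cargo free energy
# per subunit is about -14 kT at eps_SC = 6 kT (docs/methods.md).
MORSE_ALPHA_SC = 2.8
MORSE_REQ_SC = 0.5
MORSE_RCUT_SC = 2.5
# Pentamer Bottoms and Excluders are purely repulsive toward cargo.
# The excluder-cargo diameter is chosen so that intact shell faces are
# impermeable to cargo (every through-face path passes within 0.59 r* of an
# excluder, well inside the 0.71 r* repulsive core) while a missing-pentamer
# vacancy (rim clearance 1.0 r*) remains permeable, as the equilibrium
# encapsulation protocol requires.
SIGMA_BP_CARGO = 1.0
SIGMA_EXC_CARGO = 0.8

# ---------------------------------------------------------------------------
# Cargo-cargo interactions (12-6 Lennard-Jones, cut and shifted).  The
# cutoff is calibrated against the printed single-species vapor-liquid
# threshold (~1.3 kT at the working concentration): truncating at 2.5 sigma
# removes enough cohesive tail to push the measured threshold to ~1.45 kT,
# while 3.0 sigma reproduces ~1.35 kT.
# ---------------------------------------------------------------------------
SIGMA_CARGO = 1.0
RCUT_CARGO = 3.0

# ---------------------------------------------------------------------------
# Dynamics defaults
# ---------------------------------------------------------------------------
DEFAULT_TIMESTEP = 0.005
DEFAULT_FRICTION = 1.0
DEFAULT_TEMPERATURE = 1.0

# ---------------------------------------------------------------------------
# Unit mapping
# ---------------------------------------------------------------------------
R_STAR_NM = 13.0
AVOGADRO = 6.02214076e23
# Volume per particle at the 1 M standard state, in nm^3.
STANDARD_VOLUME_NM3 = 1.0e24 / AVOGADRO   # = 1.66054 nm^3


def standard_volume(r_star_nm: float = R_STAR_NM) -> float:
    """Standard-state (1 M) volume per particle in reduced units (r*^3)."""
    return STANDARD_VOLUME_NM3 / r_star_nm**3
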