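"""Species bookkeeping for the single-hepatocyte carbohydrate model.

The cell model tracks 24 dynamic metabolites distributed over three
compartments (cytosol, endoplasmic reticulum, mitochondrion).  All reaction
rates are expressed per cytosolic volume (mM/min); derivatives of ER and
mitochondrial species carry the cytosol-to-compartment volume ratio so that
mass is conserved across membranes.
"""

from __future__ import annotations

import numpy as np

# Cytosolic metabolites (mM).
CYTOSOL_SPECIES = [
    "glc", "g6p", "f6p", "f16bp", "grap", "dhap", "bpg13", "pg3", "pg2",
    "pep", "pyr", "lac", "mal", "oa", "g1p", "udpg", "f26bp", "glyc",
]
# ER metabolites (mM, ER water space).
ER_SPECIES = ["glc_er", "g6p_er"]
# Mitochondrial metabolites (mM, matrix space).
MITO_SPECIES = ["pyr_m", "pep_m", "mal_m", "oa_m"]

SPECIES = CYTOSOL_SPECIES + ER_SPECIES + MITO_SPECIES
N_SPECIES = len(SPECIES)
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

# Volume fractions of the hepatocyte occupied by each compartment.  Rates are
# written on the cytosolic basis, hence ER/mito derivatives are scaled by
# f_cyt / f_compartment.
VOLUME_FRACTIONS = {"cytosol": 0.70, "er": 0.10, "mito": 0.20}
ER_SCALE = VOLUME_FRACTIONS["cytosol"] / VOLUME_FRACTIONS["er"]
MITO_SCALE = VOLUME_FRACTIONS["cytosol"] / VOLUME_FRACTIONS["mito"]

COMPARTMENT_OF = {}
for _s in CYTOSOL_SPECIES:
    COMPARTMENT_OF[_s] = "cytosol"
for _s in ER_SPECIES:
    COMPARTMENT_OF[_s] = "er"
for _s in MITO_SPECIES:
    COMPARTMENT_OF[_s] = "mito"

# Reactions and membrane transporters of the cellular model.  Transport
# direction conventions: GLUT2/LACT positive = uptake into the cytosol;
# organelle transporters positive = flux toward the cytosol except Glc6PT
# (cytosol -> ER) and PYRT (cytosol -> mitochondrion), which follow their
# physiological forward direction.
REACTIONS = [
    "GK", "GPI", "PFK1", "ALD", "TPI", "GAPDH", "PGK", "PGM", "EN", "PK",
    "LDH", "G6PP", "PFK2", "FBP2", "FBP1", "PEPCK", "PC", "NDK", "MDH",
    "MDHM", "PPASE", "PGM1", "UGT", "GP", "GS",
    "GLC6PT", "GLCT", "PYRT", "PEPT", "MALT", "GLUT2", "LACT",
]
N_REACTIONS = len(REACTIONS)
REACTION_INDEX = {name: i for i, name in enumerate(REACTIONS)}

# Enzymes whose activity is switched by reversible phosphorylation.  gamma is
# the phosphorylated fraction (1 = fully phosphorylated = fasted/glucagon
# state).
INTERCONVERTIBLE = ["GS", "GP", "PK", "PFK2", "FBP2"]

# Net stoichiometry of each reaction on the dynamic species (columns:
# reactions, rows: species), before compartment-volume scaling.
_STOICH = {
    "GK": {"glc": -1, "g6p": +1},
    "GPI": {"g6p": -1, "f6p": +1},
    "PFK1": {"f6p": -1, "f16bp": +1},
    "ALD": {"f16bp": -1, "grap": +1, "dhap": +1},
    "TPI": {"dhap": -1, "grap": +1},
    "GAPDH": {"grap": -1, "bpg13": +1},
    "PGK": {"bpg13": -1, "pg3": +1},
    "PGM": {"pg3": -1, "pg2": +1},
    "EN": {"pg2": -1, "pep": +1},
    "PK": {"pep": -1, "pyr": +1},
    "LDH": {"pyr": -1, "lac": +1},
    "G6PP": {"g6p_er": -1, "glc_er": +1},
    "PFK2": {"f6p": -1, "f26bp": +1},
    "FBP2": {"f26bp": -1, "f6p": +1},
    "FBP1": {"f16bp": -1, "f6p": +1},
    "PEPCK": {"oa": -1, "pep": +1},
    "PC": {"pyr_m": -1, "oa_m": +1},
    "NDK": {},     # interconverts fixed nucleotides only
    "MDH": {"mal": -1, "oa": +1},
    "MDHM": {"oa_m": -1, "mal_m": +1},
    "PPASE": {},   # hydrolyses fixed pyrophosphate
    "PGM1": {"g6p": -1, "g1p": +1},
    "UGT": {"g1p": -1, "udpg": +1},
    "GP": {"glyc": -1, "g1p": +1},
    "GS": {"udpg": -1, "glyc": +1},
    "GLC6PT": {"g6p": -1, "g6p_er": +1},
    "GLCT": {"glc_er": -1, "glc": +1},
    "PYRT": {"pyr": -1, "pyr_m": +1},
    "PEPT": {"pep_m": -1, "pep": +1},
    "MALT": {"mal_m": -1, "mal": +1},
    "GLUT2": {"glc": +1},   # exchange with plasma/Disse glucose
    "LACT": {"lac": +1},    # exchange with plasma/Disse lactate
}


def stoichiometric_matrix(volume_scaled: bool = True) -> np.ndarray:
    """Return the stoichiometric matrix S (species x reactions).

    With ``volume_scaled`` the ER/mito rows are multiplied by the
    cytosol-to-compartment volume ratio so that ``rhs = S @ v`` directly
    yields concentration derivatives when rates ``v`` are on the cytosolic
    volume basis.
    """
    S = np.zeros((N_SPECIES, N_REACTIONS))
    for rxn, terms in _STOICH.items():
        j = REACTION_INDEX[rxn]
        for sp, coeff in terms.items():
            S[SPECIES_INDEX[sp], j] = coeff
    if volume_scaled:
        for sp in ER_SPECIES:
            S[SPECIES_INDEX[sp]] *= ER_SCALE
        for sp in MITO_SPECIES:
            S[SPECIES_INDEX[sp]] *= MITO_SCALE
    return S
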