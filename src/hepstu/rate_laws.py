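"""Symbolic registry of the kinetic rate laws of the cellular model.

Each entry is an infix expression over species names (see
:mod:`hepstu.species`), fixed-cofactor names, the external milieu
(``glc_x``, ``lac_x`` in mM), phosphorylation states (``g_gs`` ... the
phosphorylated fraction of each interconvertible enzyme) and kinetic
constants named ``<REACTION>_<constant>``.  Units: mM and minutes; all rates
are on the cytosolic-volume basis.

The registry is the exchange format of the model: the numerical kernel in
:mod:`hepstu.metabolic` implements the same laws by hand in vectorised
numpy, the test-suite evaluates both routes against each other, and the
SBML exporter turns these strings into MathML.

Conventions
-----------
* Reversible laws are Haldane-consistent reversible Michaelis-Menten forms;
  apparent equilibrium constants fold in the fixed cofactor ratios
  (NAD/NADH, ATP/ADP) where a cofactor pair participates.
* Interconvertible enzymes (GS, GP, PK, PFK2, FBP2) carry two limbs mixed by
  the phosphorylated fraction gamma; gamma = 1 is the fully phosphorylated
  (glucagon-dominated) form.
* Allosteric terms follow the regulators the reaction scheme names:
  fructose-2,6-bisphosphate on PFK1/FBP1, fructose-1,6-bisphosphate on PK,
  glucose-6-phosphate on phosphorylated glycogen synthase, glucose on the
  active glycogen phosphorylase, fructose-6-phosphate (GKRP-mediated) on
  glucokinase.
"""

from __future__ import annotations

# Fixed cofactor pools, mM.  Held constant during any simulation.
FIXED_COFACTORS = {
    "atp": 2.80,
    "adp": 0.80,
    "amp": 0.16,
    "nad": 0.90,
    "nadh": 0.001,
    "utp": 0.27,
    "udp": 0.09,
    "phos": 2.40,   # inorganic phosphate
    "gtp": 0.30,
    "gdp": 0.10,
    "ppi": 0.008,   # pyrophosphate
}

RATE_LAWS = {
    # Glucokinase: Hill kinetics in glucose, GKRP-mediated inhibition by Fru6P.
    "GK": "GK_Vmax * glc**GK_h / (GK_Kglc**GK_h + glc**GK_h)"
          " * GK_Kif6p / (GK_Kif6p + f6p)",
    # Glucose-6-phosphate isomerase, reversible.
    "GPI": "GPI_Vmax * (g6p - f6p/GPI_Keq)"
           " / (GPI_Kg6p + g6p + GPI_Kg6p*f6p/GPI_Kf6p)",
    # Phosphofructokinase-1: Hill in Fru6P with Fru26P2 lowering the S0.5.
    "PFK1": "PFK1_Vmax * f6p**PFK1_h"
            " / (f6p**PFK1_h + (PFK1_Kf6p/(1 + f26bp/PFK1_Kaf26bp))**PFK1_h)"
            " * atp / (PFK1_Katp + atp)",
    # Aldolase, reversible ordered uni-bi.
    "ALD": "ALD_Vmax * (f16bp - grap*dhap/ALD_Keq)"
           " / (ALD_Kf16bp * (1 + f16bp/ALD_Kf16bp + dhap/ALD_Kdhap"
           " + grap/ALD_Kgrap + dhap*grap/(ALD_Kdhap*ALD_Kgrap)))",
    # Triose-phosphate isomerase, reversible.
    "TPI": "TPI_Vmax * (dhap - grap/TPI_Keq)"
           " / (TPI_Kdhap + dhap + TPI_Kdhap*grap/TPI_Kgrap)",
    # GAPDH: apparent Keq folds in NAD/NADH and phosphate.
    "GAPDH": "GAPDH_Vmax * (grap - bpg13/(GAPDH_Keq0*nad*phos/nadh))"
             " / (GAPDH_Kgrap + grap + GAPDH_Kgrap*bpg13/GAPDH_Kbpg)",
    # Phosphoglycerate kinase: apparent Keq folds in ADP/ATP.
    "PGK": "PGK_Vmax * (bpg13 - pg3/(PGK_Keq0*adp/atp))"
           " / (PGK_Kbpg + bpg13 + PGK_Kbpg*pg3/PGK_Kpg3)",
    "PGM": "PGM_Vmax * (pg3 - pg2/PGM_Keq)"
           " / (PGM_Kpg3 + pg3 + PGM_Kpg3*pg2/PGM_Kpg2)",
    "EN": "EN_Vmax * (pg2 - pep/EN_Keq)"
          " / (EN_Kpg2 + pg2 + EN_Kpg2*pep/EN_Kpep)",
    # Pyruvate kinase: Hill in PEP, Fru16P2 lowers S0.5; the phosphorylated
    # form has a higher S0.5 and reduced capacity.
    "PK": "PK_Vmax * adp/(PK_Kadp + adp) * ("
          " (1 - g_pk) * pep**PK_h"
          " / (pep**PK_h + (PK_Kpep/(1 + f16bp/PK_Kaf16bp))**PK_h)"
          " + g_pk * PK_rp * pep**PK_h"
          " / (pep**PK_h + (PK_Kpep_p/(1 + f16bp/PK_Kaf16bp))**PK_h) )",
    # Lactate dehydrogenase: apparent Keq folds in NADH/NAD.
    "LDH": "LDH_Vmax * (pyr - lac/(LDH_Keq0*nadh/nad))"
           " / (LDH_Kpyr + pyr + LDH_Kpyr*lac/LDH_Klac)",
    # Glucose-6-phosphatase (ER lumen).
    "G6PP": "G6PP_Vmax * g6p_er / (G6PP_Km + g6p_er)",
    # PFK2 kinase limb of the bifunctional enzyme; dephosphorylated = active.
    "PFK2": "PFK2_Vmax * ((1 - g_pfk2) + g_pfk2*PFK2_rp)"
            " * f6p/(PFK2_Kf6p + f6p) * atp/(PFK2_Katp + atp)",
    # FBP2 phosphatase limb; phosphorylated = active.
    "FBP2": "FBP2_Vmax * (g_fbp2 + (1 - g_fbp2)*FBP2_rp)"
            " * f26bp/(FBP2_Kf26bp + f26bp)",
    # Fructose-1,6-bisphosphatase, inhibited by Fru26P2.
    "FBP1": "FBP1_Vmax * f16bp/(FBP1_Kf16bp + f16bp)"
            " * FBP1_Kif26bp/(FBP1_Kif26bp + f26bp)",
    # PEP carboxykinase (cytosolic, GTP-dependent).
    "PEPCK": "PEPCK_Vmax * oa/(PEPCK_Koa + oa) * gtp/(PEPCK_Kgtp + gtp)",
    # Pyruvate carboxylase (mitochondrial).
    "PC": "PC_Vmax * pyr_m/(PC_Kpyr + pyr_m) * atp/(PC_Katp + atp)"
          " * PC_Kioa/(PC_Kioa + oa_m)",
    # Nucleoside-diphosphate kinase (fixed nucleotides only).
    "NDK": "NDK_Vmax * (atp*gdp - adp*gtp/NDK_Keq)"
           " / ((NDK_Katp + atp) * (NDK_Kgdp + gdp))",
    # Cytosolic malate dehydrogenase; apparent Keq folds in NAD/NADH.
    "MDH": "MDH_Vmax * (mal - oa/(MDH_Keq0*nad/nadh))"
           " / (MDH_Kmal + mal + MDH_Kmal*oa/MDH_Koa)",
    # Mitochondrial malate dehydrogenase, OA -> Mal; the apparent Keq folds
    # in the (unmodelled) mitochondrial redox state.
    "MDHM": "MDHM_Vmax * (oa_m - mal_m/MDHM_Keq)"
            " / (MDHM_Koa + oa_m + MDHM_Koa*mal_m/MDHM_Kmal)",
    # Inorganic pyrophosphatase (fixed PPi pool).
    "PPASE": "PPASE_Vmax * ppi / (PPASE_Km + ppi)",
    # Phosphoglucomutase (Glc6P <-> Glc1P).
    "PGM1": "PGM1_Vmax * (g6p - g1p/PGM1_Keq)"
            " / (PGM1_Kg6p + g6p + PGM1_Kg6p*g1p/PGM1_Kg1p)",
    # UDP-glucose pyrophosphorylase, reversible; the fixed UTP/PPi ratio
    # poises the UDP-glucose pool.
    "UGT": "UGT_Vmax * (g1p*utp - udpg*ppi/UGT_Keq)"
           " / ((UGT_Kg1p + g1p) * (UGT_Kutp + utp) * (1 + udpg/UGT_Kudpg))",
    # Glycogen phosphorylase: phosphorylated (a) form active, inhibited by
    # free glucose; basal activity of the b form.
    "GP": "GP_Vmax * (g_gp + (1 - g_gp)*GP_rb)"
          " * glyc/(GP_Kglyc + glyc) * GP_Kiglc/(GP_Kiglc + glc)",
    # Glycogen synthase: dephosphorylated (a) form active; the b form is
    # allosterically activated by Glc6P.  Both limbs carry the storage
    # capacity term (1 - glycogen/capacity).
    "GS": "(GS_Vmax * (1 - g_gs) * udpg/(GS_Kudpg + udpg)"
          " + GS_Vmax * g_gs * GS_rb * udpg/(GS_Kudpg_b + udpg)"
          " * g6p**2/(g6p**2 + GS_Kag6p**2))"
          " * (1 - glyc/GS_capacity)",
    # ER glucose-6-phosphate transporter (cytosol -> ER).
    "GLC6PT": "GLC6PT_Vmax * (g6p/(GLC6PT_Km + g6p)"
              " - g6p_er/(GLC6PT_Km + g6p_er))",
    # ER glucose export (ER -> cytosol).
    "GLCT": "GLCT_Vmax * (glc_er/(GLCT_Km + glc_er) - glc/(GLCT_Km + glc))",
    # Mitochondrial pyruvate carrier (cytosol -> matrix).
    "PYRT": "PYRT_Vmax * (pyr/(PYRT_Km + pyr) - pyr_m/(PYRT_Km + pyr_m))",
    # PEP export from the matrix.
    "PEPT": "PEPT_Vmax * (pep_m/(PEPT_Km + pep_m) - pep/(PEPT_Km + pep))",
    # Malate export from the matrix.
    "MALT": "MALT_Vmax * (mal_m/(MALT_Km + mal_m) - mal/(MALT_Km + mal))",
    # GLUT2: symmetric facilitated diffusion, positive = uptake.
    "GLUT2": "GLUT2_Vmax * (glc_x/(GLUT2_Km + glc_x) - glc/(GLUT2_Km + glc))",
    # Monocarboxylate (lactate) transporter, positive = uptake.
    "LACT": "LACT_Vmax * (lac_x/(LACT_Km + lac_x) - lac/(LACT_Km + lac))",
}

# Reactions that are thermodynamically one-way in the model: zero substrate
# implies zero rate.
IRREVERSIBLE = [
    "GK", "PFK1", "G6PP", "PFK2", "FBP2", "FBP1", "PEPCK", "PC",
    "GP", "GS", "PPASE",
]
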