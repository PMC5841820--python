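"""Glucose-hormone and hormone-phosphorylation transfer functions.

Two empirical maps connect plasma glucose to cellular enzyme activity:

* GHT (glucose-hormone transfer): systemic plasma glucose -> systemic
  insulin and glucagon (pM).  Insulin follows a Hill curve rising with
  glucose; glucagon falls from its hypoglycaemic plateau.
* HPT (hormone-phosphorylation transfer): insulin/glucagon -> the
  phosphorylated fraction gamma of each interconvertible enzyme, modelled
  as the steady state of a kinase (PKA, glucagon-driven) /
  phosphatase (insulin-driven) cycle, which keeps gamma in (0, 1) and
  monotone in both hormones.

Pancreatic hormones reach the liver through the portal vein before systemic
dilution and extra-hepatic clearance; portal concentrations are twice the
systemic values.  Hepatic clearance is receptor mediated, so the local
removal rate is proportional to receptor occupancy (the signalling
strength) at the hepatocyte surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import INTERCONVERTIBLE

__all__ = [
    "HormoneState",
    "TransferFunctions",
    "DEFAULT_TRANSFER",
    "ght",
    "hpt",
    "gamma_from_glucose",
    "portal_boundary",
    "hormone_clearance_rate",
]

GLUCOSE_RANGE = (3.0, 15.0)  # mM validity window of the empirical curves


@dataclass(frozen=True)
class HormoneState:
    """Insulin and glucagon concentrations (pM) of one blood compartment."""

    insulin: float
    glucagon: float

    def __post_init__(self):
        if self.insulin < 0 or self.glucagon < 0:
            raise ValueError("hormone concentrations must be non-negative")


@dataclass(frozen=True)
class PortalHormoneState(HormoneState):
    """Hormone levels in incoming portal blood (type-distinct so the
    portal doubling cannot be applied twice)."""


@dataclass(frozen=True)
class TransferFunctions:
    """Parameters of the GHT/HPT curves and of receptor-mediated clearance.

    Units: hormone concentrations pM, glucose mM.  ``clear_*`` are the
    per-hepatocyte clearance capacities (amol/min of hormone removed at
    full receptor occupancy, expressed as pM*um^3/min); they are calibrated
    so that single-pass extraction at default tissue geometry falls in the
    physiological 20-40 % (glucagon) and 30-80 % (insulin) windows.
    """

    ins_basal: float = 20.0      # pM, secretion floor
    ins_max: float = 780.0       # pM, incremental amplitude
    ins_k: float = 7.2           # mM, half-effect glucose
    ins_h: float = 4.0           # Hill exponent
    gcg_min: float = 38.0        # pM, hyperglycaemic floor
    gcg_max: float = 190.0       # pM, hypoglycaemic plateau
    gcg_k: float = 5.5           # mM, half-effect glucose
    gcg_h: float = 2.5           # Hill exponent
    ins_kr: float = 150.0        # pM, insulin receptor half-occupancy
    gcg_kr: float = 800.0        # pM, glucagon response scale (near-linear)
    kin_base: float = 0.03       # basal kinase weight
    phos_base: float = 0.05      # basal phosphatase weight
    phos_ins: float = 0.30       # insulin weight on the phosphatase
    gamma_tau: float = 4.0       # min, relaxation time of gamma
    clear_ins: float = 5.0e5     # pM*um^3/min per hepatocyte at occupancy 1
    clear_gcg: float = 3.8e5     # pM*um^3/min per hepatocyte at occupancy 1


DEFAULT_TRANSFER = TransferFunctions()


def _warn_range(glucose):
    import warnings
    g = np.asarray(glucose, dtype=float)
    if np.any(g < GLUCOSE_RANGE[0]) or np.any(g > GLUCOSE_RANGE[1]):
        warnings.warn(
            f"glucose outside the {GLUCOSE_RANGE} mM calibration range of "
            "the hormone transfer functions; extrapolating", stacklevel=3)


def ght(glucose, tf: TransferFunctions = DEFAULT_TRANSFER):
    """Systemic plasma (insulin, glucagon) in pM for a plasma glucose in mM."""
    _warn_range(glucose)
    g = np.asarray(glucose, dtype=float)
    gh = g ** tf.ins_h
    ins = tf.ins_basal + tf.ins_max * gh / (tf.ins_k ** tf.ins_h + gh)
    gg = (g / tf.gcg_k) ** tf.gcg_h
    gcg = tf.gcg_min + (tf.gcg_max - tf.gcg_min) / (1.0 + gg)
    if np.ndim(glucose) == 0:
        return float(ins), float(gcg)
    return ins, gcg


def receptor_occupancy(insulin, glucagon, tf: TransferFunctions = DEFAULT_TRANSFER):
    """Fractional receptor occupancy (signalling strength) of each hormone."""
    ins = np.asarray(insulin, dtype=float)
    gcg = np.asarray(glucagon, dtype=float)
    return ins / (ins + tf.ins_kr), gcg / (gcg + tf.gcg_kr)


def hpt(insulin, glucagon, tf: TransferFunctions = DEFAULT_TRANSFER):
    """Phosphorylated fraction gamma per interconvertible enzyme.

    Returns a dict over GS, GP, PK, PFK2, FBP2.  The kinase/phosphatase
    steady state gives the same gamma for each enzyme under the default
    parameterisation; the per-enzyme interface allows enzyme-specific
    weights in configuration.
    """
    if np.any(np.asarray(insulin) < 0) or np.any(np.asarray(glucagon) < 0):
        raise ValueError("hormone concentrations must be non-negative")
    phi_ins, phi_gcg = receptor_occupancy(insulin, glucagon, tf)
    kin = tf.kin_base + phi_gcg
    phos = tf.phos_base + tf.phos_ins * phi_ins
    gamma = kin / (kin + phos)
    return {e: gamma for e in INTERCONVERTIBLE}


def gamma_from_glucose(glucose, tf: TransferFunctions = DEFAULT_TRANSFER):
    """Compose GHT and HPT: systemic plasma glucose -> gamma dict."""
    ins, gcg = ght(glucose, tf)
    return hpt(ins, gcg, tf)


def portal_boundary(systemic: HormoneState) -> PortalHormoneState:
    """Portal-vein hormone levels: twice the systemic plasma values
    (extra-hepatic clearance accounts for ~half of total clearance)."""
    return PortalHormoneState(insulin=2.0 * systemic.insulin,
                              glucagon=2.0 * systemic.glucagon)


def hormone_clearance_rate(local: HormoneState,
                           tf: TransferFunctions = DEFAULT_TRANSFER):
    """Receptor-mediated removal per hepatocyte (pM*um^3/min of hormone
    mass), linear in the signalling strength at the cell surface."""
    phi_ins, phi_gcg = receptor_occupancy(local.insulin, local.glucagon, tf)
    return tf.clear_ins * phi_ins, tf.clear_gcg * phi_gcg
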