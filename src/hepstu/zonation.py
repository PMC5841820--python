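"""Periportal-to-pericentral zonation of enzyme abundance.

Along the sinusoid the abundance of the key regulatory enzymes changes
linearly from the periportal value E_PP (cell i = 1) to the pericentral
value E_PC (cell i = N):

    E(i) = E_PP * (1 + (i-1)/(N-1) * (alpha - 1)),   alpha = E_PC / E_PP.

The mean hepatocyte (MH) is defined by the arithmetic mean
(E_PP + E_PC)/2 — the quantity calibrated against whole-organ data — and
maximal activities scale with abundance, Vmax(i)/Vmax_MH = E(i)/E_mean.
Enzymes without a measured gradient keep alpha = 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolic import EnzymeParameterSet
from .species import REACTIONS

__all__ = ["ZonationProfile", "enzyme_profile", "endpoint_params",
           "load_zonation_table"]


def load_zonation_table() -> pd.DataFrame:
    """The shipped table of periportal/pericentral abundance ratios."""
    with importlib.resources.files("hepstu.params").joinpath("zonation.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class ZonationProfile:
    """Per-enzyme abundance ratios alpha = E_PC/E_PP with optional spread.

    ``alpha`` and ``sd`` map enzyme names to values; enzymes absent from
    ``alpha`` are unzonated (alpha = 1).  ``params_mh`` holds the Vmax of
    the mean hepatocyte.
    """

    params_mh: EnzymeParameterSet
    alpha: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_cells: int = 20

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("a zonation profile needs at least 2 hepatocytes")
        for enzyme, a in self.alpha.items():
            if enzyme not in REACTIONS:
                raise ValueError(f"unknown enzyme {enzyme!r} in zonation table")
            if a <= 0:
                raise ValueError(f"alpha for {enzyme} must be > 0, got {a}")

    @classmethod
    def default(cls, n_cells: int = 20,
                params_mh: EnzymeParameterSet | None = None) -> "ZonationProfile":
        table = load_zonation_table()
        return cls(params_mh=params_mh or EnzymeParameterSet.default(),
                   alpha=dict(zip(table["enzyme"], table["alpha"])),
                   sd=dict(zip(table["enzyme"], table["sd"])),
                   n_cells=n_cells)

    def alpha_vector(self) -> np.ndarray:
        return np.array([self.alpha.get(r, 1.0) for r in REACTIONS])


def enzyme_profile(profile: ZonationProfile) -> np.ndarray:
    """Per-cell Vmax table, shape (N, n_reactions).

    Cell 1 (row 0) is the periportal hepatocyte, cell N the pericentral
    one; each column interpolates linearly with
    (E_PP + E_PC)/2 = Vmax_MH.
    """
    n = profile.n_cells
    alpha = profile.alpha_vector()
    vmax_mh = profile.params_mh.vmax
    # arithmetic mean (E_PP + E_PC)/2 = E_PP (1 + alpha)/2 = Vmax_MH
    vmax_pp = 2.0 * vmax_mh / (1.0 + alpha)
    frac = np.arange(n)[:, None] / (n - 1)
    return vmax_pp[None, :] * (1.0 + frac * (alpha[None, :] - 1.0))


def endpoint_params(profile: ZonationProfile):
    """(PPH, PCH) parameter sets: cells i = 1 and i = N of the profile."""
    table = enzyme_profile(profile)
    base = profile.params_mh
    pph = EnzymeParameterSet(base.constants, table[0], base.cofactors)
    pch = EnzymeParameterSet(base.constants, table[-1], base.cofactors)
    return pph, pch
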