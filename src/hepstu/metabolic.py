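"""Kinetic model of glycolysis, gluconeogenesis and glycogen turnover in a
single hepatocyte.

State: 24 metabolite concentrations (mM) over cytosol, ER and mitochondrion
(:mod:`hepstu.species`).  Rates are mM/min on the cytosolic-volume basis.
The only free parameters are the maximal activities (Vmax); all other
kinetic constants ship in ``params/enzymes.tsv`` with a provenance column.

Hormonal control enters through the phosphorylated fraction ``gamma`` of the
five interconvertible enzymes (GS, GP, PK, PFK2, FBP2); see
:mod:`hepstu.hormones` for the glucose -> hormone -> gamma transfer
functions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .rate_laws import FIXED_COFACTORS, RATE_LAWS
from .species import (
    INTERCONVERTIBLE,
    N_REACTIONS,
    N_SPECIES,
    REACTION_INDEX,
    REACTIONS,
    SPECIES,
    SPECIES_INDEX,
    stoichiometric_matrix,
)

__all__ = [
    "ConfigurationError",
    "EnzymeParameterSet",
    "ExternalMilieu",
    "FixedCofactors",
    "MetabolicState",
    "SteadyStateResult",
    "cell_rhs",
    "glucose_exchange_flux",
    "glycogen_timecourse",
    "reaction_rates",
    "set_point",
    "steady_state_cell",
]

GLUCOSE_FLOOR = 0.1  # mM; the model is not calibrated below this.


class ConfigurationError(ValueError):
    """A kinetic constant required by a rate law is missing or invalid."""


@dataclass(frozen=True)
class FixedCofactors:
    """Cofactor pools held constant during any simulation (mM)."""

    atp: float = FIXED_COFACTORS["atp"]
    adp: float = FIXED_COFACTORS["adp"]
    amp: float = FIXED_COFACTORS["amp"]
    nad: float = FIXED_COFACTORS["nad"]
    nadh: float = FIXED_COFACTORS["nadh"]
    utp: float = FIXED_COFACTORS["utp"]
    udp: float = FIXED_COFACTORS["udp"]
    phos: float = FIXED_COFACTORS["phos"]
    gtp: float = FIXED_COFACTORS["gtp"]
    gdp: float = FIXED_COFACTORS["gdp"]
    ppi: float = FIXED_COFACTORS["ppi"]

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FIXED_COFACTORS}


@dataclass
class ExternalMilieu:
    """Plasma-side boundary of one hepatocyte.

    ``gamma`` maps each interconvertible enzyme to its phosphorylated
    fraction in [0, 1] (1 = glucagon-dominated form).
    """

    glucose: float = 6.0          # mM
    lactate: float = 2.0          # mM
    gamma: dict = field(default_factory=lambda: {e: 0.5 for e in INTERCONVERTIBLE})

    def __post_init__(self):
        if self.glucose < GLUCOSE_FLOOR:
            raise ValueError(
                f"plasma glucose {self.glucose} mM below the {GLUCOSE_FLOOR} mM "
                "validity floor of the model"
            )
        for e in INTERCONVERTIBLE:
            g = self.gamma.get(e)
            if g is None or not (0.0 <= g <= 1.0):
                raise ValueError(f"phosphorylation state for {e} must lie in [0, 1]")

    def gamma_vector(self) -> np.ndarray:
        return np.array([self.gamma[e] for e in INTERCONVERTIBLE])


class MetabolicState:
    """Concentrations of the dynamic metabolites of one hepatocyte (mM)."""

    species = SPECIES

    def __init__(self, values):
        vec = np.asarray(values, dtype=float)
        if vec.shape != (N_SPECIES,):
            raise ValueError(f"expected {N_SPECIES} concentrations, got {vec.shape}")
        if np.any(vec < 0):
            bad = [SPECIES[i] for i in np.where(vec < 0)[0]]
            raise ValueError(f"negative concentration for {', '.join(bad)}")
        self.values = vec

    def __getitem__(self, name: str) -> float:
        return float(self.values[SPECIES_INDEX[name]])

    def as_dict(self) -> dict:
        return {s: float(v) for s, v in zip(SPECIES, self.values)}

    def replace(self, **updates) -> "MetabolicState":
        vec = self.values.copy()
        for name, val in updates.items():
            vec[SPECIES_INDEX[name]] = val
        return MetabolicState(vec)

    @classmethod
    def physiological(cls, glucose: float = 6.0) -> "MetabolicState":
        """A generic physiological starting state."""
        base = {
            "glc": glucose, "g6p": 0.15, "f6p": 0.05, "f16bp": 0.02,
            "grap": 0.01, "dhap": 0.2, "bpg13": 0.005, "pg3": 0.3,
            "pg2": 0.05, "pep": 0.15, "pyr": 0.1, "lac": 1.8,
            "mal": 0.4, "oa": 0.01, "g1p": 0.01, "udpg": 0.3,
            "f26bp": 0.005, "glyc": 150.0,
            "glc_er": glucose, "g6p_er": 0.1,
            "pyr_m": 0.1, "pep_m": 0.15, "mal_m": 0.5, "oa_m": 0.003,
        }
        return cls([base[s] for s in SPECIES])

    def __repr__(self):
        return f"MetabolicState({self.as_dict()!r})"


class EnzymeParameterSet:
    """Kinetic constants and maximal activities for every reaction.

    ``constants`` maps ``"<REACTION>_<name>"`` to its value; ``vmax`` is an
    array aligned with :data:`hepstu.species.REACTIONS`.
    """

    def __init__(self, constants: dict, vmax: np.ndarray,
                 cofactors: FixedCofactors | None = None):
        self.constants = dict(constants)
        self.vmax = np.asarray(vmax, dtype=float)
        self.cofactors = cofactors or FixedCofactors()
        self._validate()

    def _validate(self):
        if self.vmax.shape[-1] != N_REACTIONS:
            raise ConfigurationError(
                f"vmax must have {N_REACTIONS} entries, got {self.vmax.shape}")
        if np.any(self.vmax < 0):
            bad = [REACTIONS[i] for i in np.where(np.atleast_2d(self.vmax).min(0) < 0)[0]]
            raise ConfigurationError(f"negative Vmax for {', '.join(bad)}")
        for key, val in self.constants.items():
            if not np.isfinite(val) or val <= 0:
                raise ConfigurationError(f"kinetic constant {key} must be > 0")

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   cofactors: FixedCofactors | None = None) -> "EnzymeParameterSet":
        constants, vmax = {}, np.zeros(N_REACTIONS)
        seen_vmax = set()
        for _, row in table.iterrows():
            rxn, name, value = row["reaction"], row["parameter"], float(row["value"])
            if rxn not in REACTION_INDEX:
                raise ConfigurationError(f"unknown reaction {rxn!r} in parameter table")
            if name == "Vmax":
                vmax[REACTION_INDEX[rxn]] = value
                seen_vmax.add(rxn)
            else:
                constants[f"{rxn}_{name}"] = value
        missing = sorted(set(REACTIONS) - seen_vmax)
        if missing:
            raise ConfigurationError(f"missing Vmax for {', '.join(missing)}")
        return cls(constants, vmax, cofactors)

    @classmethod
    def default(cls) -> "EnzymeParameterSet":
        with importlib.resources.files("hepstu.params").joinpath("enzymes.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
        return cls.from_table(table)

    def get(self, reaction: str, name: str) -> float:
        key = f"{reaction}_{name}"
        try:
            return self.constants[key]
        except KeyError:
            raise ConfigurationError(
                f"kinetic constant {name!r} missing for enzyme {reaction}") from None

    def vmax_of(self, reaction: str) -> float:
        return float(self.vmax[REACTION_INDEX[reaction]])

    def with_vmax(self, updates: dict) -> "EnzymeParameterSet":
        vmax = self.vmax.copy()
        for rxn, val in updates.items():
            vmax[REACTION_INDEX[rxn]] = val
        return EnzymeParameterSet(self.constants, vmax, self.cofactors)

    def scaled(self, factors: dict) -> "EnzymeParameterSet":
        """Scale the Vmax of selected reactions by per-reaction factors."""
        vmax = self.vmax.copy()
        for rxn, fac in factors.items():
            vmax[REACTION_INDEX[rxn]] *= fac
        return EnzymeParameterSet(self.constants, vmax, self.cofactors)

    def copy(self) -> "EnzymeParameterSet":
        return EnzymeParameterSet(self.constants, self.vmax.copy(), self.cofactors)


# stoichiometric matrix with compartment-volume scaling applied
S_MATRIX = stoichiometric_matrix(volume_scaled=True)


def _mm(s, km):
    return s / (km + s)


def reaction_rates_kernel(C: np.ndarray, vmax: np.ndarray, gamma: np.ndarray,
                          glc_x, lac_x, k: dict, cof: dict) -> np.ndarray:
    """Vectorised evaluation of all rate laws.

    ``C``: concentrations, shape (..., 24); ``vmax``: shape (..., 32) or
    (32,); ``gamma``: phosphorylated fractions ordered as
    :data:`hepstu.species.INTERCONVERTIBLE`, shape (..., 5); ``glc_x`` /
    ``lac_x``: external glucose/lactate, scalar or shape (...).  Returns
    rates with shape (..., 32) in mM/min (cytosolic basis).

    This is the hand-written numerical transcription of
    :data:`hepstu.rate_laws.RATE_LAWS`; the test-suite checks the two
    against each other term by term.
    """
    C = np.asarray(C, dtype=float)
    sp = {name: C[..., i] for i, name in enumerate(SPECIES)}
    glc, g6p, f6p, f16bp = sp["glc"], sp["g6p"], sp["f6p"], sp["f16bp"]
    grap, dhap, bpg13 = sp["grap"], sp["dhap"], sp["bpg13"]
    pg3, pg2, pep, pyr, lac = sp["pg3"], sp["pg2"], sp["pep"], sp["pyr"], sp["lac"]
    mal, oa, g1p, udpg = sp["mal"], sp["oa"], sp["g1p"], sp["udpg"]
    f26bp, glyc = sp["f26bp"], sp["glyc"]
    glc_er, g6p_er = sp["glc_er"], sp["g6p_er"]
    pyr_m, pep_m, mal_m, oa_m = sp["pyr_m"], sp["pep_m"], sp["mal_m"], sp["oa_m"]

    gamma = np.asarray(gamma, dtype=float)
    g_gs, g_gp, g_pk = gamma[..., 0], gamma[..., 1], gamma[..., 2]
    g_pfk2, g_fbp2 = gamma[..., 3], gamma[..., 4]

    atp, adp = cof["atp"], cof["adp"]
    nad, nadh = cof["nad"], cof["nadh"]
    utp, phos = cof["utp"], cof["phos"]
    gtp, gdp, ppi = cof["gtp"], cof["gdp"], cof["ppi"]

    v = np.zeros(C.shape[:-1] + (N_REACTIONS,))

    def put(name, val):
        v[..., REACTION_INDEX[name]] = val

    glch = glc ** k["GK_h"]
    put("GK", glch / (k["GK_Kglc"] ** k["GK_h"] + glch)
        * k["GK_Kif6p"] / (k["GK_Kif6p"] + f6p))
    put("GPI", (g6p - f6p / k["GPI_Keq"])
        / (k["GPI_Kg6p"] + g6p + k["GPI_Kg6p"] * f6p / k["GPI_Kf6p"]))
    kf = k["PFK1_Kf6p"] / (1.0 + f26bp / k["PFK1_Kaf26bp"])
    f6ph = f6p ** k["PFK1_h"]
    put("PFK1", f6ph / (f6ph + kf ** k["PFK1_h"]) * atp / (k["PFK1_Katp"] + atp))
    put("ALD", (f16bp - grap * dhap / k["ALD_Keq"])
        / (k["ALD_Kf16bp"] * (1.0 + f16bp / k["ALD_Kf16bp"] + dhap / k["ALD_Kdhap"]
           + grap / k["ALD_Kgrap"] + dhap * grap / (k["ALD_Kdhap"] * k["ALD_Kgrap"]))))
    put("TPI", (dhap - grap / k["TPI_Keq"])
        / (k["TPI_Kdhap"] + dhap + k["TPI_Kdhap"] * grap / k["TPI_Kgrap"]))
    keq_gapdh = k["GAPDH_Keq0"] * nad * phos / nadh
    put("GAPDH", (grap - bpg13 / keq_gapdh)
        / (k["GAPDH_Kgrap"] + grap + k["GAPDH_Kgrap"] * bpg13 / k["GAPDH_Kbpg"]))
    keq_pgk = k["PGK_Keq0"] * adp / atp
    put("PGK", (bpg13 - pg3 / keq_pgk)
        / (k["PGK_Kbpg"] + bpg13 + k["PGK_Kbpg"] * pg3 / k["PGK_Kpg3"]))
    put("PGM", (pg3 - pg2 / k["PGM_Keq"])
        / (k["PGM_Kpg3"] + pg3 + k["PGM_Kpg3"] * pg2 / k["PGM_Kpg2"]))
    put("EN", (pg2 - pep / k["EN_Keq"])
        / (k["EN_Kpg2"] + pg2 + k["EN_Kpg2"] * pep / k["EN_Kpep"]))
    peph = pep ** k["PK_h"]
    act = 1.0 + f16bp / k["PK_Kaf16bp"]
    kp_d = (k["PK_Kpep"] / act) ** k["PK_h"]
    kp_p = (k["PK_Kpep_p"] / act) ** k["PK_h"]
    put("PK", adp / (k["PK_Kadp"] + adp)
        * ((1.0 - g_pk) * peph / (peph + kp_d)
           + g_pk * k["PK_rp"] * peph / (peph + kp_p)))
    keq_ldh = k["LDH_Keq0"] * nadh / nad
    put("LDH", (pyr - lac / keq_ldh)
        / (k["LDH_Kpyr"] + pyr + k["LDH_Kpyr"] * lac / k["LDH_Klac"]))
    put("G6PP", g6p_er / (k["G6PP_Km"] + g6p_er))
    put("PFK2", ((1.0 - g_pfk2) + g_pfk2 * k["PFK2_rp"])
        * f6p / (k["PFK2_Kf6p"] + f6p) * atp / (k["PFK2_Katp"] + atp))
    put("FBP2", (g_fbp2 + (1.0 - g_fbp2) * k["FBP2_rp"])
        * f26bp / (k["FBP2_Kf26bp"] + f26bp))
    put("FBP1", f16bp / (k["FBP1_Kf16bp"] + f16bp)
        * k["FBP1_Kif26bp"] / (k["FBP1_Kif26bp"] + f26bp))
    put("PEPCK", oa / (k["PEPCK_Koa"] + oa) * gtp / (k["PEPCK_Kgtp"] + gtp))
    put("PC", pyr_m / (k["PC_Kpyr"] + pyr_m) * atp / (k["PC_Katp"] + atp)
        * k["PC_Kioa"] / (k["PC_Kioa"] + oa_m))
    put("NDK", (atp * gdp - adp * gtp / k["NDK_Keq"])
        / ((k["NDK_Katp"] + atp) * (k["NDK_Kgdp"] + gdp)))
    keq_mdh = k["MDH_Keq0"] * nad / nadh
    put("MDH", (mal - oa / keq_mdh)
        / (k["MDH_Kmal"] + mal + k["MDH_Kmal"] * oa / k["MDH_Koa"]))
    put("MDHM", (oa_m - mal_m / k["MDHM_Keq"])
        / (k["MDHM_Koa"] + oa_m + k["MDHM_Koa"] * mal_m / k["MDHM_Kmal"]))
    put("PPASE", ppi / (k["PPASE_Km"] + ppi))
    put("PGM1", (g6p - g1p / k["PGM1_Keq"])
        / (k["PGM1_Kg6p"] + g6p + k["PGM1_Kg6p"] * g1p / k["PGM1_Kg1p"]))
    put("UGT", (g1p * utp - udpg * ppi / k["UGT_Keq"])
        / ((k["UGT_Kg1p"] + g1p) * (k["UGT_Kutp"] + utp)
           * (1.0 + udpg / k["UGT_Kudpg"])))
    put("GP", (g_gp + (1.0 - g_gp) * k["GP_rb"])
        * glyc / (k["GP_Kglyc"] + glyc) * k["GP_Kiglc"] / (k["GP_Kiglc"] + glc))
    cap = 1.0 - glyc / k["GS_capacity"]
    put("GS", ((1.0 - g_gs) * udpg / (k["GS_Kudpg"] + udpg)
               + g_gs * k["GS_rb"] * udpg / (k["GS_Kudpg_b"] + udpg)
               * g6p ** 2 / (g6p ** 2 + k["GS_Kag6p"] ** 2)) * cap)
    put("GLC6PT", _mm(g6p, k["GLC6PT_Km"]) - _mm(g6p_er, k["GLC6PT_Km"]))
    put("GLCT", _mm(glc_er, k["GLCT_Km"]) - _mm(glc, k["GLCT_Km"]))
    put("PYRT", _mm(pyr, k["PYRT_Km"]) - _mm(pyr_m, k["PYRT_Km"]))
    put("PEPT", _mm(pep_m, k["PEPT_Km"]) - _mm(pep, k["PEPT_Km"]))
    put("MALT", _mm(mal_m, k["MALT_Km"]) - _mm(mal, k["MALT_Km"]))
    put("GLUT2", _mm(glc_x, k["GLUT2_Km"]) - _mm(glc, k["GLUT2_Km"]))
    put("LACT", _mm(lac_x, k["LACT_Km"]) - _mm(lac, k["LACT_Km"]))

    return v * vmax


def _check_constants(params: EnzymeParameterSet):
    """Fail loudly, naming the enzyme, if any constant a rate law needs is
    absent from the parameter set."""
    import re
    known = set(params.constants)
    for rxn, law in RATE_LAWS.items():
        for token in re.findall(r"\b[A-Z][A-Z0-9]*_[A-Za-z0-9_]+\b", law):
            if token.endswith("_Vmax"):
                continue
            if token not in known:
                raise ConfigurationError(
                    f"kinetic constant {token.split('_', 1)[1]!r} missing for "
                    f"enzyme {rxn}")


def reaction_rates(state: MetabolicState, params: EnzymeParameterSet,
                   milieu: ExternalMilieu) -> np.ndarray:
    """Per-reaction flux vector (mM/min, cytosolic basis) ordered as
    :data:`hepstu.species.REACTIONS`."""
    _check_constants(params)
    return reaction_rates_kernel(
        state.values, params.vmax, milieu.gamma_vector(),
        milieu.glucose, milieu.lactate, params.constants,
        params.cofactors.as_dict())


def cell_rhs(state: MetabolicState, params: EnzymeParameterSet,
             milieu: ExternalMilieu) -> np.ndarray:
    """Time derivative of every metabolite (mM/min), ``S @ v`` with
    compartment-volume corrections for ER and mitochondrial species."""
    return S_MATRIX @ reaction_rates(state, params, milieu)


def _rhs_vec(x, params, gamma, glc_x, lac_x):
    v = reaction_rates_kernel(x, params.vmax, gamma, glc_x, lac_x,
                              params.constants, params.cofactors.as_dict())
    return S_MATRIX @ v


@dataclass
class SteadyStateResult:
    state: MetabolicState
    residual: float
    converged: bool
    iterations: int


def _numeric_jacobian(fun, x, f0=None, rel=1e-7):
    f0 = fun(x) if f0 is None else f0
    n = x.size
    J = np.empty((f0.size, n))
    for i in range(n):
        h = rel * max(abs(x[i]), 1e-8)
        xp = x.copy()
        xp[i] += h
        J[:, i] = (fun(xp) - f0) / h
    return J


def steady_state_cell(params: EnzymeParameterSet, milieu: ExternalMilieu,
                      initial: MetabolicState | None = None,
                      tol: float = 1e-9, max_newton: int = 60,
                      integrate_first: float = 2000.0) -> SteadyStateResult:
    """Steady state of the cell model: damped Newton in log-concentration
    space, with a stiff time-integration fallback.

    Raises ``RuntimeError`` (with the residual) on non-convergence; the
    convergence criterion is the infinity norm of the right-hand side below
    ``tol`` mM/min.
    """
    initial = initial or MetabolicState.physiological(milieu.glucose)
    gamma = milieu.gamma_vector()
    glc_x, lac_x = milieu.glucose, milieu.lactate

    def rhs(x):
        return _rhs_vec(np.maximum(x, 1e-12), params, gamma, glc_x, lac_x)

    U_LO, U_HI = np.log(1e-12), np.log(1e4)

    def newton(x0):
        """Damped Newton in log space; returns (x, residual, iters)."""
        u = np.clip(np.log(np.maximum(x0, 1e-12)), U_LO, U_HI)

        def rhs_u(uvec):
            return rhs(np.exp(np.clip(uvec, U_LO, U_HI)))

        f = rhs_u(u)
        iters = 0
        for _ in range(max_newton):
            iters += 1
            nrm = np.max(np.abs(f))
            if nrm < tol:
                break
            J = _numeric_jacobian(rhs_u, u, f0=f)
            try:
                du = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                du = np.linalg.lstsq(J, -f, rcond=None)[0]
            du = np.clip(du, -2.0, 2.0)
            lam, improved = 1.0, False
            for _ls in range(14):
                f_try = rhs_u(u + lam * du)
                if np.all(np.isfinite(f_try)) and np.max(np.abs(f_try)) < nrm:
                    u, f, improved = u + lam * du, f_try, True
                    break
                lam *= 0.5
            if not improved:
                break  # stalled; caller integrates further
        return np.exp(np.clip(u, U_LO, U_HI)), float(np.max(np.abs(f))), iters

    x = initial.values.copy()
    iterations = 0
    horizon = max(integrate_first, 1.0)
    best_x, best_res = x, float(np.max(np.abs(rhs(x))))
    for attempt in range(4):
        # Pre-relax by stiff integration: glycogen equilibrates on the scale
        # of days, so on retries the horizon grows tenfold.
        sol = solve_ivp(lambda t, y: rhs(y), (0.0, horizon), best_x,
                        method="BDF", rtol=1e-8, atol=1e-10)
        if sol.success and np.all(np.isfinite(sol.y[:, -1])):
            best_x = np.maximum(sol.y[:, -1], 1e-12)
            best_res = float(np.max(np.abs(rhs(best_x))))
        x_new, res, iters = newton(best_x)
        iterations += iters
        if res < best_res:
            best_x, best_res = x_new, res
        if best_res < tol:
            return SteadyStateResult(MetabolicState(best_x), best_res, True,
                                     iterations)
        horizon *= 10.0

    raise RuntimeError(
        f"steady state not found: residual {best_res:.3e} mM/min exceeds {tol}")


def glucose_exchange_flux(params: EnzymeParameterSet, glc_range,
                          lactate: float = 2.0, gamma_of_glucose=None,
                          initial: MetabolicState | None = None):
    """Net steady-state GLUT2 uptake (mM/min, cytosolic basis; positive =
    uptake) for each plasma glucose value.

    ``gamma_of_glucose`` maps plasma glucose to the phosphorylation-state
    dict; by default the systemic glucose-hormone and
    hormone-phosphorylation transfer functions are composed.
    """
    if gamma_of_glucose is None:
        from .hormones import gamma_from_glucose
        gamma_of_glucose = gamma_from_glucose
    glc_range = np.atleast_1d(np.asarray(glc_range, dtype=float))
    gef = np.empty_like(glc_range)
    state = initial
    for i, glc in enumerate(glc_range):
        milieu = ExternalMilieu(glucose=float(glc), lactate=lactate,
                                gamma=gamma_of_glucose(float(glc)))
        res = steady_state_cell(params, milieu, initial=state)
        state = res.state  # warm start along the sweep
        rates = reaction_rates(state, params, milieu)
        gef[i] = rates[REACTION_INDEX["GLUT2"]]
    return gef


def set_point(params: EnzymeParameterSet, lactate: float = 2.0,
              glc_lo: float = 3.0, glc_hi: float = 12.0,
              tol: float = 0.01, gamma_of_glucose=None) -> float:
    """Plasma glucose at which the net glucose exchange flux is zero (mM),
    found by bisection on the monotone steady-state GEF curve."""
    if gamma_of_glucose is None:
        from .hormones import gamma_from_glucose
        gamma_of_glucose = gamma_from_glucose

    cache = {}

    def gef(glc):
        if glc not in cache:
            cache[glc] = float(glucose_exchange_flux(
                params, [glc], lactate, gamma_of_glucose)[0])
        return cache[glc]

    lo, hi = glc_lo, glc_hi
    flo, fhi = gef(lo), gef(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"no set-point: GEF({lo})={flo:.4g}, GEF({hi})={fhi:.4g} "
            "do not bracket zero")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gef(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def glycogen_timecourse(params: EnzymeParameterSet, protocol,
                        lactate: float = 2.0, gamma_of_glucose=None,
                        output_dt: float = 10.0, fast_hours: float = 24.0):
    """Glycogen trajectory under a piecewise-constant plasma-glucose
    schedule.

    ``protocol``: sequence of ``(duration_h, glucose_mM)`` phases.  The
    initial state is the endpoint of a ``fast_hours`` fast at 4 mM, as in
    the starvation-refeeding protocol.  Returns ``(t_hours, glycogen_mM,
    states)`` sampled every ``output_dt`` minutes.
    """
    if gamma_of_glucose is None:
        from .hormones import gamma_from_glucose
        gamma_of_glucose = gamma_from_glucose

    def integrate_phase(x0, glucose, minutes, t_eval):
        milieu = ExternalMilieu(glucose=glucose, lactate=lactate,
                                gamma=gamma_of_glucose(glucose))
        gamma = milieu.gamma_vector()

        def f(t, y):
            return _rhs_vec(np.maximum(y, 1e-12), params, gamma,
                            glucose, lactate)

        sol = solve_ivp(f, (0.0, minutes), x0, method="BDF",
                        rtol=1e-8, atol=1e-10, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"integrator failed at t={sol.t[-1]:.1f} min of the "
                f"{glucose} mM phase: {sol.message}")
        return sol

    # pre-fast at 4 mM
    x = MetabolicState.physiological(4.0).values
    sol = integrate_phase(x, 4.0, fast_hours * 60.0, None)
    x = np.maximum(sol.y[:, -1], 1e-12)

    times, glyco, states = [0.0], [x[SPECIES_INDEX["glyc"]]], [x.copy()]
    t0 = 0.0
    for duration_h, glucose in protocol:
        minutes = duration_h * 60.0
        t_eval = np.arange(output_dt, minutes + 0.5 * output_dt, output_dt)
        sol = integrate_phase(x, glucose, minutes, t_eval)
        x = np.maximum(sol.y[:, -1], 1e-12)
        times.extend((t0 + sol.t / 60.0).tolist())
        glyco.extend(sol.y[SPECIES_INDEX["glyc"]].tolist())
        states.extend(list(sol.y.T))
        t0 += duration_h
    return np.asarray(times), np.asarray(glyco), np.asarray(states)
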