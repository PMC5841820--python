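"""Assembly and solution of the full sinusoidal-tissue-unit ODE system.

One STU couples N hepatocytes (kinetic cell model, per-cell Vmax from the
zonation profile) to the sinusoid and space-of-Disse transport model.  The
state vector of the default 20-cell unit has 889 entries:

* per cell (30 x N): 24 metabolite concentrations, the phosphorylated
  fraction of the 5 interconvertible enzymes (first-order relaxation to the
  hormone-phosphorylation transfer target set by Disse hormones), and the
  labelled-water tracer concentration of the cell water space;
* per domain: 7 sinusoid species (glucose, lactate, insulin, glucagon,
  RBC, albumin, labelled water) and 6 Disse species (no RBC - red cells
  cannot pass the fenestrae);
* 4 vascular boundary nodes x 7 species: two pre-sinusoidal dispersion
  compartments (they shape the arrival of an injected bolus), the portal
  inflow node and the central-vein collecting node;
* one cumulative lymph-drainage volume (a pure output integrator, excluded
  from steady-state residuals).

Sign conventions, used everywhere: axial flow is positive from portal to
central; transmural flux is positive vessel -> Disse; the porto-venous
difference is portal minus venous, so positive means net hepatic uptake.
Venous values are read from the central collecting node.

Units: concentrations mM (metabolites/tracers) or pM (hormones), time
minutes, volumes um^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize._numdiff import approx_derivative

from .hormones import (DEFAULT_TRANSFER, TransferFunctions, ght,
                       receptor_occupancy)
from .metabolic import MetabolicState, S_MATRIX, reaction_rates_kernel
from .microcirculation import (STUGeometry, SystemicParams,
                               TRANSPORT_DEFAULTS, flow_field,
                               solute_exchange_conductances)
from .species import (INTERCONVERTIBLE, N_SPECIES, REACTION_INDEX,
                      VOLUME_FRACTIONS)
from .zonation import ZonationProfile, enzyme_profile

__all__ = [
    "STUSystem", "STUResult", "assemble_stu", "steady_state_stu",
    "porto_venous_curve", "sinusoid_length_effect", "indicator_dilution",
    "hormone_extraction", "gamma_variate_input",
]

VASC_SPECIES = ["glc", "lac", "ins", "gcg", "rbc", "alb", "wat"]
DISSE_SPECIES = ["glc", "lac", "ins", "gcg", "alb", "wat"]
N_VASC, N_DISSE = len(VASC_SPECIES), len(DISSE_SPECIES)
CELL_STATES = N_SPECIES + len(INTERCONVERTIBLE) + 1  # 24 + 5 + 1 = 30
N_BOUNDARY = 4  # disp1, disp2, portal, central

TRACER_NAME = {"rbc": "rbc", "albumin": "alb", "water": "wat"}


class STUSystem:
    """Assembled coupled ODE system of one sinusoidal tissue unit."""

    def __init__(self, geometry: STUGeometry, profile: ZonationProfile,
                 systemic: SystemicParams | None = None,
                 transfer: TransferFunctions | None = None,
                 transport: dict | None = None):
        if geometry.n_cells != profile.n_cells:
            raise ValueError(
                f"geometry has {geometry.n_cells} cells but the zonation "
                f"profile has {profile.n_cells}")
        self.geometry = geometry
        self.profile = profile
        self.systemic = systemic or SystemicParams()
        self.transfer = transfer or DEFAULT_TRANSFER
        self.transport = transport or TRANSPORT_DEFAULTS
        self.params = profile.params_mh
        self.vmax_table = enzyme_profile(profile)       # (N, n_reactions)

        n = geometry.n_cells
        self.n_cells = n
        self.n_states = CELL_STATES * n + N_VASC * n + N_DISSE * n \
            + N_VASC * N_BOUNDARY + 1

        # index offsets
        self.off_sin = CELL_STATES * n
        self.off_dis = self.off_sin + N_VASC * n
        self.off_bnd = self.off_dis + N_DISSE * n
        self.off_lymph = self.off_bnd + N_VASC * N_BOUNDARY

        # steady water-flow field (um^3/min)
        ff = flow_field(geometry, self.systemic)
        self.flow = ff
        self.qv = ff.q_vessel * 60.0
        self.qd = ff.q_disse * 60.0
        self.jw = ff.j_wall * 60.0
        self.ql = ff.q_lymph * 60.0

        # volumes (um^3)
        self.v_vessel = geometry.vessel_volume
        self.v_disse = geometry.disse_volume
        self.v_cell = geometry.cell_volume
        self.v_cyt = VOLUME_FRACTIONS["cytosol"] * self.v_cell
        self.v_disp = 2.0 * self.v_vessel
        self.v_port = self.v_vessel
        self.v_cent = self.v_vessel

        # per-species exchange conductances (um^3/min)
        self.k_fen, self.k_ax_v, self.k_ax_d, self.cell_ps = {}, {}, {}, {}
        name_map = {"glc": "glucose", "lac": "lactate", "ins": "insulin",
                    "gcg": "glucagon", "rbc": "rbc", "alb": "albumin",
                    "wat": "water"}
        for sp in VASC_SPECIES:
            props = self.transport[name_map[sp]]
            kf, kav, kad, ps = solute_exchange_conductances(geometry, props)
            self.k_fen[sp] = kf * 60.0
            self.k_ax_v[sp] = kav * 60.0
            self.k_ax_d[sp] = kad * 60.0
            self.cell_ps[sp] = ps * 60.0
        self._permeant = {sp: self.k_fen[sp] > 0 for sp in VASC_SPECIES}
        self._sparsity = None

    # ---- state vector helpers -------------------------------------------
    def split(self, y: np.ndarray):
        n = self.n_cells
        cells = y[: self.off_sin].reshape(n, CELL_STATES)
        sin = y[self.off_sin: self.off_dis].reshape(n, N_VASC)
        dis = y[self.off_dis: self.off_bnd].reshape(n, N_DISSE)
        bnd = y[self.off_bnd: self.off_lymph].reshape(N_BOUNDARY, N_VASC)
        return cells, sin, dis, bnd, y[self.off_lymph]

    def initial_state(self, portal_glc: float, portal_lac: float = 2.0):
        """Start all compartments at the portal composition."""
        n = self.n_cells
        ins_sys, gcg_sys = ght(min(max(portal_glc, 3.0), 15.0), self.transfer)
        ins_p, gcg_p = 2.0 * ins_sys, 2.0 * gcg_sys
        cells = np.tile(
            np.concatenate([MetabolicState.physiological(portal_glc).values,
                            0.5 * np.ones(len(INTERCONVERTIBLE)), [0.0]]),
            (n, 1))
        vasc = np.array([portal_glc, portal_lac, ins_p, gcg_p, 0.0, 0.0, 0.0])
        dis = vasc[[0, 1, 2, 3, 5, 6]]
        y = np.concatenate([cells.ravel(), np.tile(vasc, n),
                            np.tile(dis, n), np.tile(vasc, N_BOUNDARY), [0.0]])
        return y

    def inflow_vector(self, portal_glc: float, portal_lac: float = 2.0):
        ins_sys, gcg_sys = ght(min(max(portal_glc, 3.0), 15.0), self.transfer)
        return np.array([portal_glc, portal_lac, 2.0 * ins_sys,
                         2.0 * gcg_sys, 0.0, 0.0, 0.0])

    # ---- right-hand side ------------------------------------------------
    def rhs(self, y: np.ndarray, c_in: np.ndarray,
            metabolism: bool = True) -> np.ndarray:
        n = self.n_cells
        tf = self.transfer
        cells, sin, dis, bnd, _ = self.split(y)
        dy = np.zeros_like(y)
        d_cells, d_sin, d_dis, d_bnd, _ = self.split(dy)

        qv, qd, jw, ql = self.qv, self.qd, self.jw, self.ql
        q_in = qv[0]

        # boundary chain: inflow -> disp1 -> disp2 -> portal
        d_bnd[0] = q_in * (c_in - bnd[0]) / self.v_disp
        d_bnd[1] = q_in * (bnd[0] - bnd[1]) / self.v_disp
        d_bnd[2] = q_in * (bnd[1] - bnd[2]) / self.v_port
        # central collecting node fed by the last segment
        d_bnd[3] = qv[n] * (sin[-1] - bnd[3]) / self.v_cent

        dis_cols = [VASC_SPECIES.index(sp) for sp in DISSE_SPECIES]

        for j, sp in enumerate(VASC_SPECIES):
            c = sin[:, j]
            up = np.concatenate([[bnd[2, j]], c])      # upwind donors
            conv = qv[:-1] * up[:-1] - qv[1:] * up[1:]
            diff = np.zeros(n)
            kav = self.k_ax_v[sp]
            if kav > 0 and n > 1:
                flux = kav * np.diff(c)                # face i+1/2
                diff[:-1] += flux
                diff[1:] -= flux
            d_sin[:, j] += (conv + diff) / self.v_vessel
            if self._permeant[sp]:
                jd = DISSE_SPECIES.index(sp)
                cd = dis[:, jd]
                # transmural: convective (Starling water drag) + diffusive
                wall = jw * np.where(jw > 0, c, cd) + self.k_fen[sp] * (c - cd)
                d_sin[:, j] -= wall / self.v_vessel
                d_dis[:, jd] += wall / self.v_disse

        for jd, sp in enumerate(DISSE_SPECIES):
            cd = dis[:, jd]
            up = np.concatenate([[cd[0]], cd])         # closed portal end
            conv = qd[:-1] * up[:-1] - qd[1:] * up[1:]
            conv[0] = -qd[1] * cd[0]
            diff = np.zeros(n)
            kad = self.k_ax_d[sp]
            if kad > 0 and n > 1:
                flux = kad * np.diff(cd)
                diff[:-1] += flux
                diff[1:] -= flux
            d_dis[:, jd] += (conv + diff) / self.v_disse

        # lymph drains the last Disse node (solute leaves with the fluid)
        dy[self.off_lymph] = ql

        # hepatocyte water tracer
        ps_w = self.cell_ps["wat"]
        cw = cells[:, CELL_STATES - 1]
        dwat = ps_w * (dis[:, DISSE_SPECIES.index("wat")] - cw)
        d_cells[:, CELL_STATES - 1] += dwat / self.v_cell
        d_dis[:, DISSE_SPECIES.index("wat")] -= dwat / self.v_disse

        # hormone clearance at the Disse/cell interface and gamma dynamics
        ins_d = dis[:, DISSE_SPECIES.index("ins")]
        gcg_d = dis[:, DISSE_SPECIES.index("gcg")]
        phi_ins, phi_gcg = receptor_occupancy(ins_d, gcg_d, tf)
        d_dis[:, DISSE_SPECIES.index("ins")] -= tf.clear_ins * phi_ins / self.v_disse
        d_dis[:, DISSE_SPECIES.index("gcg")] -= tf.clear_gcg * phi_gcg / self.v_disse
        kin = tf.kin_base + phi_gcg
        phos = tf.phos_base + tf.phos_ins * phi_ins
        gamma_target = kin / (kin + phos)
        gam = cells[:, N_SPECIES: N_SPECIES + len(INTERCONVERTIBLE)]
        d_cells[:, N_SPECIES: N_SPECIES + len(INTERCONVERTIBLE)] += \
            (gamma_target[:, None] - gam) / tf.gamma_tau

        # metabolism, coupled to Disse glucose/lactate
        if metabolism:
            conc = np.maximum(cells[:, :N_SPECIES], 1e-12)
            glc_d = np.maximum(dis[:, DISSE_SPECIES.index("glc")], 1e-9)
            lac_d = np.maximum(dis[:, DISSE_SPECIES.index("lac")], 1e-9)
            v = reaction_rates_kernel(conc, self.vmax_table,
                                      np.clip(gam, 0.0, 1.0), glc_d, lac_d,
                                      self.params.constants,
                                      self.params.cofactors.as_dict())
            d_cells[:, :N_SPECIES] += v @ S_MATRIX.T
            # transporter mass flux back-reacts on the Disse pools
            glut2 = v[:, REACTION_INDEX["GLUT2"]]
            lact = v[:, REACTION_INDEX["LACT"]]
            d_dis[:, DISSE_SPECIES.index("glc")] -= glut2 * self.v_cyt / self.v_disse
            d_dis[:, DISSE_SPECIES.index("lac")] -= lact * self.v_cyt / self.v_disse
        return dy

    # ---- Jacobian sparsity (for the stiff integrator) --------------------
    def jac_sparsity(self) -> sparse.csr_matrix:
        if self._sparsity is not None:
            return self._sparsity
        n, m = self.n_cells, self.n_states
        rows, cols = [], []

        def link(a, b):
            rows.append(a)
            cols.append(b)

        def block(idx_a, idx_b):
            for a in idx_a:
                for b in idx_b:
                    link(a, b)

        cell_idx = [list(range(i * CELL_STATES, (i + 1) * CELL_STATES))
                    for i in range(n)]
        sin_idx = [[self.off_sin + i * N_VASC + j for j in range(N_VASC)]
                   for i in range(n)]
        dis_idx = [[self.off_dis + i * N_DISSE + j for j in range(N_DISSE)]
                   for i in range(n)]
        bnd_idx = [[self.off_bnd + i * N_VASC + j for j in range(N_VASC)]
                   for i in range(N_BOUNDARY)]

        for i in range(n):
            block(cell_idx[i], cell_idx[i] + dis_idx[i])
            block(dis_idx[i], dis_idx[i] + cell_idx[i] + sin_idx[i])
            block(sin_idx[i], sin_idx[i] + dis_idx[i])
            if i > 0:
                block(sin_idx[i], sin_idx[i - 1])
                block(dis_idx[i], dis_idx[i - 1])
            if i < n - 1:
                block(sin_idx[i], sin_idx[i + 1])
                block(dis_idx[i], dis_idx[i + 1])
        block(sin_idx[0], bnd_idx[2])
        block(bnd_idx[0], bnd_idx[0])
        block(bnd_idx[1], bnd_idx[0] + bnd_idx[1])
        block(bnd_idx[2], bnd_idx[1] + bnd_idx[2])
        block(bnd_idx[3], bnd_idx[3] + sin_idx[n - 1])
        for j in range(m):
            link(j, j)
        link(self.off_lymph, self.off_lymph)
        self._sparsity = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m))
        return self._sparsity


@dataclass
class STUResult:
    """Steady-state solution of one STU at fixed portal composition."""

    portal_glucose: float
    venous_glucose: float
    delta_glu_pv: float            # portal - venous, mM; positive = uptake
    per_cell_gef: np.ndarray       # mM/min cytosolic basis, positive = uptake
    sinusoid_glucose: np.ndarray
    disse_glucose: np.ndarray
    cell_glucose: np.ndarray
    insulin_extraction: float      # 1 - venous/portal
    glucagon_extraction: float
    glycogen: np.ndarray           # per-cell, mM glucosyl units
    residual: float
    state: np.ndarray
    system: STUSystem

    @property
    def mass_balance_error(self) -> float:
        """Relative error of portal glucose inflow vs venous outflow plus
        net cellular uptake (and the small lymph export)."""
        sys_ = self.system
        n = sys_.n_cells
        cells, sin, dis, bnd, _ = sys_.split(self.state)
        inflow = sys_.qv[0] * self.portal_glucose
        outflow = sys_.qv[n] * bnd[3, VASC_SPECIES.index("glc")]
        lymph = sys_.ql * dis[-1, DISSE_SPECIES.index("glc")]
        uptake = float(np.sum(self.per_cell_gef) * sys_.v_cyt)
        return abs(inflow - outflow - lymph - uptake) / abs(inflow)


def assemble_stu(geometry: STUGeometry | None = None,
                 profile: ZonationProfile | None = None,
                 systemic: SystemicParams | None = None,
                 transfer: TransferFunctions | None = None,
                 transport: dict | None = None) -> STUSystem:
    """Build the coupled STU system (convection + diffusion + transmural
    exchange + membrane transport + metabolism + hormone clearance)."""
    geometry = geometry or STUGeometry()
    profile = profile or ZonationProfile.default(n_cells=geometry.n_cells)
    return STUSystem(geometry, profile, systemic, transfer, transport)


def _steady_state(system: STUSystem, y0, c_in, tol=1e-7,
                  horizon=4e4, metabolism=True):
    """Integrate to near-steady state, then polish with sparse Newton.

    The lymph integrator row is masked (its derivative is a constant
    drainage rate by construction).
    """
    mask = np.ones(system.n_states, bool)
    mask[system.off_lymph] = False

    def f(y):
        return system.rhs(y, c_in, metabolism=metabolism)

    def f_masked(y):
        r = f(y)
        return r[mask]

    y = y0.copy()
    sp = system.jac_sparsity()
    best, best_res = y, np.inf
    for attempt in range(3):
        sol = solve_ivp(lambda t, v: f(v), (0.0, horizon), y, method="BDF",
                        rtol=1e-8, atol=1e-10, jac_sparsity=sp)
        if sol.success and np.all(np.isfinite(sol.y[:, -1])):
            y = sol.y[:, -1]
        res = float(np.max(np.abs(f_masked(y))))
        if res < best_res:
            best, best_res = y.copy(), res
        # sparse Newton polish
        sp_masked = sp[mask][:, mask]
        for _ in range(25):
            r = f_masked(y)
            nrm = float(np.max(np.abs(r)))
            if nrm < tol:
                return y, nrm
            J = approx_derivative(lambda v: f_masked(_embed(y, v, mask)),
                                  y[mask], f0=r, sparsity=sp_masked,
                                  method="2-point")
            try:
                step = sparse.linalg.spsolve(sparse.csc_matrix(J), -r)
            except Exception:
                break
            lam, ok = 1.0, False
            for _ls in range(10):
                y_try = _embed(y, y[mask] + lam * step, mask)
                r_try = f_masked(y_try)
                if np.all(np.isfinite(r_try)) and np.max(np.abs(r_try)) < nrm:
                    y, ok = y_try, True
                    break
                lam *= 0.5
            if not ok:
                break
        res = float(np.max(np.abs(f_masked(y))))
        if res < best_res:
            best, best_res = y.copy(), res
        if best_res < tol:
            return best, best_res
        y = best
        horizon *= 10.0
    raise RuntimeError(
        f"STU steady state not reached: residual {best_res:.3e} exceeds {tol}")


def _embed(y_full, y_masked, mask):
    out = y_full.copy()
    out[mask] = y_masked
    return out


def steady_state_stu(system: STUSystem, portal_glucose: float,
                     portal_lactate: float = 2.0, y0=None,
                     tol: float = 1e-7) -> STUResult:
    """Steady state of the whole STU at fixed portal composition."""
    c_in = system.inflow_vector(portal_glucose, portal_lactate)
    y0 = system.initial_state(portal_glucose, portal_lactate) if y0 is None else y0
    y, res = _steady_state(system, y0, c_in, tol=tol)
    return _result_from_state(system, y, portal_glucose, res)


def _result_from_state(system, y, portal_glucose, res) -> STUResult:
    cells, sin, dis, bnd, _ = system.split(y)
    glc_d = dis[:, DISSE_SPECIES.index("glc")]
    lac_d = dis[:, DISSE_SPECIES.index("lac")]
    gam = np.clip(cells[:, N_SPECIES:N_SPECIES + len(INTERCONVERTIBLE)], 0, 1)
    v = reaction_rates_kernel(np.maximum(cells[:, :N_SPECIES], 1e-12),
                              system.vmax_table, gam, glc_d, lac_d,
                              system.params.constants,
                              system.params.cofactors.as_dict())
    gef = v[:, REACTION_INDEX["GLUT2"]]
    venous = float(bnd[3, VASC_SPECIES.index("glc")])
    c_in = system.inflow_vector(portal_glucose)
    iv, ic = VASC_SPECIES.index("ins"), VASC_SPECIES.index("gcg")
    ins_extr = 1.0 - float(bnd[3, iv]) / c_in[iv] if c_in[iv] > 0 else 0.0
    gcg_extr = 1.0 - float(bnd[3, ic]) / c_in[ic] if c_in[ic] > 0 else 0.0
    return STUResult(
        portal_glucose=portal_glucose, venous_glucose=venous,
        delta_glu_pv=portal_glucose - venous, per_cell_gef=gef,
        sinusoid_glucose=sin[:, VASC_SPECIES.index("glc")].copy(),
        disse_glucose=glc_d.copy(),
        cell_glucose=cells[:, 0].copy(),
        insulin_extraction=ins_extr, glucagon_extraction=gcg_extr,
        glycogen=cells[:, MetabolicState.species.index("glyc")].copy(),
        residual=res, state=y, system=system)


def porto_venous_curve(system: STUSystem, portal_grid,
                       portal_lactate: float = 2.0):
    """Steady-state porto-venous glucose difference over a portal-glucose
    grid, warm-starting each point from the previous one."""
    results, y0 = [], None
    for glc in portal_grid:
        r = steady_state_stu(system, float(glc), portal_lactate, y0=y0)
        y0 = r.state
        results.append(r)
    return np.array([r.delta_glu_pv for r in results]), results


def stu_set_point(system: STUSystem, lo=3.0, hi=15.0, tol=0.05,
                  portal_lactate: float = 2.0) -> float:
    """Portal glucose at which the porto-venous difference crosses zero."""
    cache = {}

    def dpv(g):
        if g not in cache:
            cache[g] = steady_state_stu(system, g, portal_lactate).delta_glu_pv
        return cache[g]

    flo, fhi = dpv(lo), dpv(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("porto-venous difference does not cross zero in range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if dpv(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sinusoid_length_effect(params_mh=None, n_values=(15, 20, 25),
                           portal_values=(4.0, 7.0, 10.0),
                           systemic: SystemicParams | None = None):
    """Porto-venous glucose difference for STUs of different length
    (length scales with cell number at fixed 15 um per hepatocyte).

    Returns an array of shape (len(n_values), len(portal_values)).
    """
    out = np.empty((len(n_values), len(portal_values)))
    for a, n in enumerate(n_values):
        geom = STUGeometry(length=15.0 * n, n_cells=n)
        profile = ZonationProfile.default(n_cells=n, params_mh=params_mh)
        system = STUSystem(geom, profile, systemic)
        y0 = None
        for b, glc in enumerate(portal_values):
            r = steady_state_stu(system, glc, y0=y0)
            y0 = r.state
            out[a, b] = r.delta_glu_pv
    return out


def hormone_extraction(system: STUSystem, portal_glucose: float,
                       y0=None) -> tuple:
    """Single-pass (insulin, glucagon) extraction fractions at steady
    state."""
    r = steady_state_stu(system, portal_glucose, y0=y0)
    return r.insulin_extraction, r.glucagon_extraction


# ---- indicator dilution --------------------------------------------------

def gamma_variate_input(t, a: float = 2.0, b: float = 10.0,
                        t0: float = 0.0):
    """Gamma-variate bolus (normalised to unit peak) approximating the
    measured red-cell arrival curve; ``t`` in seconds."""
    tt = np.maximum(np.asarray(t, dtype=float) - t0, 0.0)
    peak = (a * b) ** a * np.exp(-a)
    return (tt ** a) * np.exp(-tt / b) / peak


def _tracer_matrix(system: STUSystem, tracer: str):
    """Sparse generator of the linear tracer subsystem (units: 1/s).

    State order: disp1, disp2, portal, vessel 0..n-1, central,
    then (if permeant) disse 0..n-1, then (if cell-permeant) cells 0..n-1.
    Returns (A, input_index, outflow_index, volumes).
    """
    sp = TRACER_NAME[tracer]
    n = system.n_cells
    qv, qd, jw, ql = (system.qv / 60.0, system.qd / 60.0,
                      system.jw / 60.0, system.ql / 60.0)
    kf = system.k_fen[sp] / 60.0
    kav = system.k_ax_v[sp] / 60.0
    kad = system.k_ax_d[sp] / 60.0
    ps = system.cell_ps[sp] / 60.0
    permeant = system._permeant[sp]
    in_cell = ps > 0

    idx_disp1, idx_disp2, idx_port = 0, 1, 2
    idx_ves = [3 + i for i in range(n)]
    idx_cent = 3 + n
    m = 4 + n
    idx_dis = idx_cel = None
    if permeant:
        idx_dis = [m + i for i in range(n)]
        m += n
    if in_cell:
        idx_cel = [m + i for i in range(n)]
        m += n

    vols = np.empty(m)
    vols[idx_disp1] = vols[idx_disp2] = system.v_disp
    vols[idx_port] = system.v_port
    vols[idx_cent] = system.v_cent
    for i in idx_ves:
        vols[i] = system.v_vessel
    if permeant:
        for i in idx_dis:
            vols[i] = system.v_disse
    if in_cell:
        for i in idx_cel:
            vols[i] = system.v_cell

    A = sparse.lil_matrix((m, m))

    def flow(src, dst, q):
        """Convective transfer src -> dst carrying q um^3/s."""
        if src is not None:
            A[src, src] -= q / vols[src]
            if dst is not None:
                A[dst, src] += q / vols[dst]

    def exch(a_, b_, k):
        A[a_, a_] -= k / vols[a_]
        A[a_, b_] += k / vols[a_]
        A[b_, b_] -= k / vols[b_]
        A[b_, a_] += k / vols[b_]

    q_in = qv[0]
    flow(idx_disp1, idx_disp2, q_in)
    flow(idx_disp2, idx_port, q_in)
    flow(idx_port, idx_ves[0], q_in)
    for i in range(n - 1):
        flow(idx_ves[i], idx_ves[i + 1], qv[i + 1])
    flow(idx_ves[-1], idx_cent, qv[n])
    flow(idx_cent, None, qv[n])       # leaves the unit
    for i in range(n):
        if permeant:
            flow(idx_ves[i], idx_dis[i], max(jw[i], 0.0))
            exch(idx_ves[i], idx_dis[i], kf)
        if kav > 0 and i < n - 1:
            exch(idx_ves[i], idx_ves[i + 1], kav)
    if permeant:
        for i in range(n - 1):
            flow(idx_dis[i], idx_dis[i + 1], qd[i + 1])
            if kad > 0:
                exch(idx_dis[i], idx_dis[i + 1], kad)
        flow(idx_dis[-1], None, ql)   # lymph
        if in_cell:
            for i in range(n):
                exch(idx_dis[i], idx_cel[i], ps)
    return A.tocsr(), idx_disp1, idx_cent, vols


def indicator_dilution(system: STUSystem, tracer: str,
                       input_function=gamma_variate_input,
                       t_max: float = 400.0, dt: float = 0.25):
    """Outflow concentration-time curve of a labelled indicator.

    The tracer is passive (metabolism plays no role), so the subsystem is
    linear and solved on its own.  ``input_function(t)`` gives the inflow
    concentration (arbitrary units) at time t seconds.  Returns
    ``(t_seconds, outflow_concentration)``.
    """
    if tracer not in TRACER_NAME:
        raise ValueError(f"unknown tracer {tracer!r}; choose from "
                         f"{sorted(TRACER_NAME)}")
    A, idx_in, idx_out, vols = _tracer_matrix(system, tracer)
    q_in = system.qv[0] / 60.0
    b = np.zeros(A.shape[0])
    b[idx_in] = q_in / vols[idx_in]

    def f(t, c):
        return A @ c + b * input_function(t)

    t_eval = np.arange(0.0, t_max + dt / 2, dt)
    sol = solve_ivp(f, (0.0, t_max), np.zeros(A.shape[0]), method="LSODA",
                    t_eval=t_eval, rtol=1e-8, atol=1e-12)
    return sol.t, sol.y[idx_out]


def half_life_decay(t: np.ndarray, c: np.ndarray) -> float:
    """Time (s) from the curve maximum until the outflow first stays below
    half of the maximum."""
    i_peak = int(np.argmax(c))
    half = 0.5 * c[i_peak]
    below = np.where(c[i_peak:] < half)[0]
    if below.size == 0:
        return float("nan")
    j = i_peak + below[0]
    # linear interpolation between the bracketing samples
    t1, t2 = t[j - 1], t[j]
    c1, c2 = c[j - 1], c[j]
    t_half = t1 + (c1 - half) * (t2 - t1) / (c1 - c2)
    return float(t_half - t[i_peak])
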