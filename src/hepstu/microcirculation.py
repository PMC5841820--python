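"""Blood and water flow and solute exchange physics of one sinusoidal
tissue unit (STU).

The STU is a straight tube: a sinusoid of radius ``r`` and length ``L``
surrounded by the space of Disse (annulus of thickness ``d``) and a layer
of hepatocytes (thickness ``h``), axially discretised into N domains of
extent ``L/N``, one per hepatocyte.  Elementary processes:

* axial blood flow in the vessel: Hagen-Poiseuille law for a cylinder;
* axial water flow in the Disse space: Hagen-Poiseuille law for a hollow
  cylinder (annulus);
* transmural filtration across the fenestrated endothelium: Starling-type,
  driven by hydrostatic minus effective oncotic pressure difference;
* diffusive solute exchange vessel <-> Disse through the fenestrae and
  axial diffusion inside each compartment;
* lymph drainage from the central end of the Disse space.

Pressures are solved on a resistor network with Dirichlet portal/central
boundary conditions; the resulting steady water-flow field is what the
solute transport of :mod:`hepstu.stu` rides on.

Units: lengths um, flows um^3/s, pressures mmHg at the interface
(converted to Pa internally), diffusivities um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STUGeometry", "SystemicParams", "SpeciesTransportProps", "FlowField",
    "TRANSPORT_DEFAULTS", "vessel_flow", "disse_flow", "flow_field",
    "transmural_water_flux", "solute_exchange_conductances",
    "rbc_transit_time", "perfused_systemic",
]

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class STUGeometry:
    """Tissue architecture of one STU (lengths in um)."""

    radius: float = 4.0            # sinusoid lumen radius
    length: float = 300.0          # sinusoid length
    disse: float = 1.5             # thickness of the space of Disse
    hepatocyte: float = 30.0       # thickness of the hepatocyte layer
    n_cells: int = 20              # hepatocytes (= domains) along the sinusoid
    fenestration: float = 0.07     # open-area fraction of the endothelium
    endothelium: float = 0.5       # diffusion path length across the wall

    def __post_init__(self):
        for name in ("radius", "length", "disse", "hepatocyte",
                     "fenestration", "endothelium"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry parameter {name} must be > 0")
        if self.n_cells < 2:
            raise ValueError("need at least 2 hepatocytes")
        if self.fenestration > 1:
            raise ValueError("fenestration is an area fraction <= 1")

    @property
    def dx(self) -> float:
        """Axial extent of one domain (um); length = n_cells * dx."""
        return self.length / self.n_cells

    @property
    def r_disse(self) -> float:
        return self.radius + self.disse

    @property
    def r_outer(self) -> float:
        return self.r_disse + self.hepatocyte

    @property
    def vessel_volume(self) -> float:
        """Lumen volume per domain (um^3)."""
        return np.pi * self.radius ** 2 * self.dx

    @property
    def disse_volume(self) -> float:
        return np.pi * (self.r_disse ** 2 - self.radius ** 2) * self.dx

    @property
    def cell_volume(self) -> float:
        return np.pi * (self.r_outer ** 2 - self.r_disse ** 2) * self.dx

    @property
    def fenestral_area(self) -> float:
        """Open exchange area vessel<->Disse per domain (um^2)."""
        return 2.0 * np.pi * self.radius * self.dx * self.fenestration


@dataclass(frozen=True)
class SystemicParams:
    """Pressures, viscosities and exchange coefficients driving the flow.

    ``viscosity`` is the effective viscosity of sinusoidal blood (mPa s);
    it absorbs the hemodynamic resistance of cells and endothelial
    irregularities, hence is well above plasma viscosity.  The default
    portal-central pressure difference is calibrated so that the default
    geometry carries the in vivo per-sinusoid blood flow implied by
    CT-perfusion organ means; `perfused_systemic` returns the high-flow
    preset of an in situ pump-perfused preparation.
    """

    p_portal: float = 6.00         # mmHg
    p_central: float = 5.78        # mmHg
    p_lymph: float = 5.20          # mmHg, interstitial/lymph outlet
    pi_plasma: float = 25.0        # mmHg, plasma oncotic pressure
    pi_disse: float = 20.0         # mmHg, Disse (lymph) oncotic pressure
    sigma: float = 0.10            # oncotic reflection of the leaky wall
    viscosity: float = 20.0        # mPa s, effective sinusoidal blood
    viscosity_disse: float = 50.0  # mPa s, effective (matrix-hindered) Disse fluid
    lp_wall: float = 0.05          # um^3/s per um^2 per mmHg, wall conductivity
    lymph_conductance: float = 15.0  # um^3/s per mmHg, Disse -> lymph outlet

    def __post_init__(self):
        if self.p_portal <= self.p_central:
            raise ValueError("portal pressure must exceed central pressure")
        if self.viscosity <= 0 or self.viscosity_disse <= 0:
            raise ValueError("viscosity must be > 0")

    @property
    def delta_p(self) -> float:
        return self.p_portal - self.p_central


def perfused_systemic() -> SystemicParams:
    """Pressure preset of the pump-perfused isolated-organ preparation
    (high trans-sinusoidal gradient, used for indicator-dilution work)."""
    return SystemicParams(p_portal=8.0, p_central=2.0, p_lymph=1.8)


@dataclass(frozen=True)
class SpeciesTransportProps:
    """Diffusivities and compartment accessibility of one blood-borne
    species."""

    name: str
    d_plasma: float               # um^2/s in plasma
    d_disse: float                # um^2/s in the Disse space
    in_disse: bool = True         # can cross the fenestrae
    in_cell: bool = False         # enters hepatocytes passively
    cell_ps: float = 0.0          # um^3/s per domain, membrane permeability


TRANSPORT_DEFAULTS = {
    "glucose": SpeciesTransportProps("glucose", 600.0, 400.0, True, False),
    "lactate": SpeciesTransportProps("lactate", 900.0, 600.0, True, False),
    "insulin": SpeciesTransportProps("insulin", 150.0, 100.0, True, False),
    "glucagon": SpeciesTransportProps("glucagon", 180.0, 120.0, True, False),
    "rbc": SpeciesTransportProps("rbc", 0.0, 0.0, False, False),
    "albumin": SpeciesTransportProps("albumin", 60.0, 20.0, True, False),
    "water": SpeciesTransportProps("water", 2000.0, 1500.0, True, True,
                                   cell_ps=5.0e4),
}


@dataclass(frozen=True)
class FlowField:
    """Steady water-flow solution on the STU network.

    ``q_vessel``: axial flow across the N+1 vessel faces (um^3/s, portal
    face first); ``q_disse``: same for the Disse annulus; ``j_wall``:
    transmural filtration per domain (um^3/s, vessel -> Disse positive);
    ``q_lymph``: drainage from the last Disse node; ``p_vessel`` /
    ``p_disse``: node pressures (mmHg).
    """

    q_vessel: np.ndarray
    q_disse: np.ndarray
    j_wall: np.ndarray
    q_lymph: float
    p_vessel: np.ndarray
    p_disse: np.ndarray


def _g_vessel(geom: STUGeometry, sys: SystemicParams) -> float:
    """Axial Poiseuille conductance of one vessel segment (um^3/s/mmHg)."""
    # eta mPa*s = 1e-3 Pa*s; lengths um: pi r^4 / (8 eta dx) in um^4 /
    # (Pa*s*um) = um^3/(Pa*s); times 133.322 Pa/mmHg.
    return (np.pi * geom.radius ** 4
            / (8.0 * sys.viscosity * 1e-3 * geom.dx)) * MMHG_TO_PA


def _g_disse(geom: STUGeometry, sys: SystemicParams) -> float:
    """Axial conductance of one Disse (annulus) segment (um^3/s/mmHg)."""
    r1, r2 = geom.radius, geom.r_disse
    shape = (r2 ** 4 - r1 ** 4
             - (r2 ** 2 - r1 ** 2) ** 2 / np.log(r2 / r1))
    return (np.pi * shape
            / (8.0 * sys.viscosity_disse * 1e-3 * geom.dx)) * MMHG_TO_PA


def flow_field(geom: STUGeometry, sys: SystemicParams) -> FlowField:
    """Solve the coupled vessel/Disse pressure network.

    Vessel nodes see Dirichlet portal/central pressures through half-segment
    resistances at the two ends; the Disse space is closed at the portal end
    and drains into the lymph at the central end.  Transmural filtration is
    Starling-like with the effective oncotic offset sigma*(pi_pl - pi_d)
    applied across the fenestrated wall area.
    """
    n = geom.n_cells
    gv, gd = _g_vessel(geom, sys), _g_disse(geom, sys)
    gt = sys.lp_wall * geom.fenestral_area  # um^3/s/mmHg per domain
    oncotic = sys.sigma * (sys.pi_plasma - sys.pi_disse)

    # Unknowns: P_v[0..n-1], P_d[0..n-1]
    A = np.zeros((2 * n, 2 * n))
    b = np.zeros(2 * n)
    for i in range(n):
        row = i
        # vessel axial neighbours (boundary faces have half resistance)
        if i == 0:
            A[row, i] += 2 * gv
            b[row] += 2 * gv * sys.p_portal
        else:
            A[row, i] += gv
            A[row, i - 1] -= gv
        if i == n - 1:
            A[row, i] += 2 * gv
            b[row] += 2 * gv * sys.p_central
        else:
            A[row, i] += gv
            A[row, i + 1] -= gv
        # transmural leak
        A[row, i] += gt
        A[row, n + i] -= gt
        b[row] += gt * oncotic
    for i in range(n):
        row = n + i
        A[row, n + i] += gt
        A[row, i] -= gt
        b[row] -= gt * oncotic
        if i > 0:
            A[row, n + i] += gd
            A[row, n + i - 1] -= gd
        if i < n - 1:
            A[row, n + i] += gd
            A[row, n + i + 1] -= gd
        if i == n - 1:
            A[row, n + i] += sys.lymph_conductance
            b[row] += sys.lymph_conductance * sys.p_lymph
    p = np.linalg.solve(A, b)
    p_v, p_d = p[:n], p[n:]

    q_vessel = np.empty(n + 1)
    q_vessel[0] = 2 * gv * (sys.p_portal - p_v[0])
    q_vessel[1:n] = gv * (p_v[:-1] - p_v[1:])
    q_vessel[n] = 2 * gv * (p_v[-1] - sys.p_central)
    j_wall = gt * (p_v - p_d - oncotic)
    q_disse = np.zeros(n + 1)
    for i in range(1, n):
        q_disse[i] = gd * (p_d[i - 1] - p_d[i])
    q_lymph = sys.lymph_conductance * (p_d[-1] - sys.p_lymph)
    q_disse[n] = q_lymph
    return FlowField(q_vessel, q_disse, j_wall, float(q_lymph), p_v, p_d)


def vessel_flow(geom: STUGeometry, sys: SystemicParams) -> np.ndarray:
    """Volumetric blood flow across each vessel face (um^3/s); for an
    impermeable wall this reduces to pi r^4 dp / (8 eta L)."""
    return flow_field(geom, sys).q_vessel


def disse_flow(geom: STUGeometry, sys: SystemicParams) -> np.ndarray:
    """Water flow across each axial face of the Disse annulus (um^3/s)."""
    return flow_field(geom, sys).q_disse


def transmural_water_flux(geom: STUGeometry, sys: SystemicParams) -> np.ndarray:
    """Starling filtration vessel -> Disse per domain (um^3/s)."""
    return flow_field(geom, sys).j_wall


def annulus_conductance(geom: STUGeometry, sys: SystemicParams) -> float:
    """Closed-form axial conductance of the Disse annulus per segment
    (um^3/s/mmHg); exposed for cross-checking against the network."""
    return _g_disse(geom, sys)


def solute_exchange_conductances(geom: STUGeometry,
                                 props: SpeciesTransportProps):
    """Diffusive exchange coefficients for one species (um^3/s).

    Returns ``(k_fen, k_ax_vessel, k_ax_disse, cell_ps)``: fenestral
    vessel<->Disse conductance per domain, axial conductances between
    adjacent vessel / Disse nodes, and the hepatocyte membrane permeability
    (zero unless the species enters cells passively).
    """
    if props.d_plasma < 0 or props.d_disse < 0:
        raise ValueError(f"species {props.name} lacks a valid diffusivity")
    k_fen = (props.d_plasma * geom.fenestral_area / geom.endothelium
             if props.in_disse else 0.0)
    a_vessel = np.pi * geom.radius ** 2
    a_disse = np.pi * (geom.r_disse ** 2 - geom.radius ** 2)
    k_ax_v = props.d_plasma * a_vessel / geom.dx
    k_ax_d = props.d_disse * a_disse / geom.dx if props.in_disse else 0.0
    cell_ps = props.cell_ps if props.in_cell else 0.0
    return k_fen, k_ax_v, k_ax_d, cell_ps


def rbc_transit_time(geom: STUGeometry, sys: SystemicParams) -> float:
    """Convective transit time of red blood cells through the sinusoid (s):
    lumen volume over inflow."""
    q_in = flow_field(geom, sys).q_vessel[0]
    return geom.n_cells * geom.vessel_volume / q_in
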