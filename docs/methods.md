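# Methods

`hepstu` models the sinusoidal tissue unit (STU) of the liver: one
sinusoid, its space of Disse, and the adjacent layer of hepatocytes,
discretised into N axial domains (one hepatocyte per domain, 15 µm axial
extent).  The porto-venous glucose difference ΔGlu_PV = c_portal −
c_venous (positive = net hepatic uptake) is the tissue-scale output.

## Cellular kinetic model

The hepatocyte model covers glycolysis, gluconeogenesis and glycogen
turnover: 24 dynamic metabolites in three compartments (18 cytosolic, 2
ER, 4 mitochondrial) and 32 reactions/transporters.  Rate laws are
Haldane-consistent reversible Michaelis–Menten forms with the allosteric
couplings that dominate hepatic carbohydrate control: fructose-2,6-P₂
activation of PFK1 and inhibition of FBP1, fructose-1,6-P₂ feed-forward
activation of pyruvate kinase, Glc6P activation of the phosphorylated
glycogen synthase, glucose inhibition of active phosphorylase, GKRP-type
Fru6P inhibition of glucokinase, and oxaloacetate product inhibition of
pyruvate carboxylase (which bounds anaplerotic cycling).  ATP/ADP/AMP,
NAD(H), UTP/UDP, GTP/GDP, Pi and PPi are fixed pools; their ratios are
folded into apparent equilibrium constants.  ER and mitochondrial
derivatives carry the cytosol-to-compartment volume ratio (0.70 : 0.10 :
0.20 of cell volume), so mass is conserved across membranes.

Every kinetic constant ships in `params/enzymes.tsv` with a provenance
column.  Michaelis and equilibrium constants are standard enzyme-kinetics
values; the maximal activities (Vmax) are the model's only free
parameters and were calibrated, in this order, against: (i) the zero-flux
plasma-glucose set-points of the periportal and pericentral hepatocyte
(7.0 and 5.4 mM), (ii) physiological steady-state metabolite ranges
(`params/metabolite_ranges.tsv`), (iii) the whole-liver glucose exchange
rates at 4 and 10 mM portal glucose after conversion through the tissue
model (−131.8 and +75.8 µmol/g/h), and (iv) glycogen dynamics filling
from a fasted ~50–100 mM to a fed ~400 mM (glucosyl units, cytosolic
basis) within a 24 h refeeding.  Because a set-point is a zero crossing,
it is invariant under a uniform rescaling of all Vmax; the overall flux
amplitude (iii) was therefore fixed last by one global factor.

Steady states are found by damped Newton iteration in
log-concentration space (guaranteeing positivity) with a stiff BDF
integration fallback; the convergence criterion is ‖dx/dt‖∞ < 1e-9
mM/min.  Time courses use BDF with rtol 1e-8, atol 1e-10 throughout.

## Zonation

Enzyme abundance varies linearly from the periportal cell (i = 1) to the
pericentral cell (i = N): E(i) = E_PP·(1 + (i−1)/(N−1)·(α−1)) with α =
E_PC/E_PP.  The mean hepatocyte (MH) is defined by the arithmetic mean
(E_PP+E_PC)/2 — the quantity calibrated against whole-organ data — rather
than by a grid index, so even and odd N behave identically.  The shipped
ratio table (`params/zonation.tsv`) zonates the glycolytic limb
pericentrally (pyruvate kinase α = 3, the best-documented gradient;
GK/PFK1/PFK2-FBP2 1.2–1.3), the gluconeogenic limb periportally
(G6PP/FBP1/PEPCK/PC α = 0.76–0.9) and glycogen synthase/phosphorylase
mildly periportally.  Apart from the 3-fold PK gradient these ratios are
calibration values chosen within reported experimental spreads so that the
endpoint cells reproduce the 7.0/5.4 mM set-points around the calibrated
MH; they are configuration, not constants.

## Hormone signalling

Plasma glucose maps to systemic insulin and glucagon through empirical
Hill curves (insulin 20→800 pM rising around 7.2 mM; glucagon 190→38 pM
falling around 5.5 mM).  Portal concentrations are twice systemic
(extra-hepatic clearance is about half of total clearance).  The
phosphorylated fraction γ of the five interconvertible enzymes (GS, GP,
PK, PFK2, FBP2) is the steady state of a kinase/phosphatase cycle: the
kinase weight follows glucagon receptor occupancy, the phosphatase weight
insulin receptor occupancy, which keeps γ in (0,1) and monotone in both
hormones.  The insulin receptor half-saturates at 250 pM while the
glucagon response is effectively linear over the physiological range
(scale 800 pM).  This asymmetry matters at tissue scale: doubling both
hormones at the portal inlet is then net glucagon-dominant, and together
with the stronger single-pass extraction of insulin (≈80 % maximum)
than glucagon (≈25 %) it shifts the whole unit's set-point (~7.1–7.5 mM)
above both cellular set-points — the same mechanism the organ-scale data
show.  Hepatic clearance is receptor-mediated, so each cell removes
hormone from its Disse compartment at a rate proportional to local
receptor occupancy; the two capacity constants are calibrated so the
extraction maxima over portal glucose 3–15 mM sit at ≈79 % (insulin) and
≈25 % (glucagon), inside the measured 30–80 % and 20–40 % windows.
Inside the STU, γ is a dynamic state relaxing to its hormone target with
a 4 min time constant; at steady state it equals the algebraic transfer
value exactly.

## Microcirculation

Blood flow in the sinusoid follows the Hagen–Poiseuille law for a
cylinder, water flow in the Disse space the hollow-cylinder (annulus)
form; transmural filtration across the fenestrated endothelium is
Starling-like with a small effective oncotic offset (σ = 0.1, leaky
wall), and the Disse space drains into the lymph at the central end
(≈0.3 % of blood flow).  Pressures are solved on a resistor network with
Dirichlet portal/central boundaries.  Solutes ride this flow field with
upwind convection, axial diffusion, fenestral diffusion (open-area
fraction 0.07, 0.5 µm path) and, for glucose/lactate, carrier-mediated
membrane transport into the cells.  Red cells are confined to the lumen;
albumin reaches the Disse space; labelled water also equilibrates with
the cell water.

Two pressure presets are provided.  The default (in vivo) preset carries
≈492 µm³/s per sinusoid — the value implied by dividing a mean
CT-perfusion flow of 44.3 ml/100ml/min among 1.5·10⁹ sinusoids per
100 ml — using an effective sinusoidal viscosity of 20 mPa·s and a
trans-sinusoidal pressure difference of 0.22 mmHg.  The perfused-organ
preset (Δp = 6 mmHg) reproduces the hemodynamics of pump-perfused
isolated-liver preparations: a ≈1 s red-cell transit and labelled-water
outflow half-lives of ≈50–70 s.  Indicator-dilution work and sensitivity
analysis use the perfused preset; metabolic steady states, extraction and
the functiogram use the in vivo preset.  At the in vivo flow the
hypoglycaemic glucose release is limited by precursor delivery rather
than by enzyme capacity, which is why enzyme control is probed under
perfused flow.

## The assembled unit

With 20 hepatocytes the state vector has 889 entries: 20 cells × (24
metabolites + 5 phosphorylation states + 1 tracer-water) + 20 sinusoid
nodes × 7 species + 20 Disse nodes × 6 species + 4 vascular boundary
nodes × 7 (two pre-sinusoidal dispersion compartments, the portal node,
the central collecting node) + 1 cumulative lymph-volume integrator.
The sparse Jacobian structure (nearest-neighbour axial coupling, dense
within-cell blocks) is supplied to the BDF integrator; steady states are
polished by a sparse Newton iteration to ‖rhs‖∞ < 1e-7 (the lymph
integrator row, a pure output accumulator, is excluded).  Venous values
are read from the central collecting node, which at steady state equals
the last sinusoid segment.

Indicator dilution is solved on the reduced linear tracer subsystem
(tracers do not react), driven by a gamma-variate inflow bolus
(t²·e^(−t/10 s), unit peak) that stands for the dispersed arrival of an
upstream injection; its two parameters are configuration
(`defaults.yaml`) fitted once to the measured red-cell curve shape.  The
half-life decay time of a curve is the time from its maximum to the
first crossing of half the maximum.

## Physiological states: steady vs fasting-transient

Carbon balance caps steady-state glucose production at half the lactate
delivery (portal lactate 2 mM stands for all gluconeogenic precursors),
i.e. ΔGlu_PV ≥ −1 mM at the default flow.  Organ-scale hypoglycaemic
production rates of order −130 µmol/g/h therefore necessarily include
glycogenolysis and belong to a quasi-steady fasting transient, not to a
strict steady state.  The functiogram consequently evaluates portal
glucose below 6 mM in a defined fasting state: the unit is initialised at
its fed steady state (7.5 mM) and read 6 h after the portal glucose is
lowered, while glycogen is still being mobilised.  The 6 h readout is the
one calibrated protocol constant, fitted to the whole-liver hypoglycaemic
production rate; uptake states (≥ 6 mM) use the true steady state.

## Monte-Carlo variability

Tissue variability is sampled from truncated Gaussians (vessel diameter
8 ± 0.2 µm, Disse thickness 1.5 ± 0.1 µm, hepatocyte layer 30 ± 0.8 µm,
fenestration 0.07 ± 0.008, cell number 20 ± 0.6 clipped to [15, 25]) and
a relative pressure factor (1 ± 0.05); enzyme ratios α are drawn from
uniform spreads (`zonation.tsv`).  The structural spreads are calibrated
so the sampled labelled-water half-life band reproduces the measured
≈50–70 s dispersion; the enzymatic spreads dominate the ≈20–30 %
variability of ΔGlu_PV.  One master seed drives every experiment;
per-unit substreams are derived deterministically (`default_rng([seed,
i])`).

## Sensitivity analysis

S(p) = [ΔGlu_PV(p(1+ε)) − ΔGlu_PV(p(1−ε))] / (2·ε·ΔGlu_PV(p)) with
ε = 0.05 — the relative central difference (a verbally equivalent
formula that omits the factor 2 of the central difference circulates in
the literature; the implementation uses the consistent form).
Sensitivities are evaluated at 4 mM (fasted) and 10 mM (fed) portal
glucose under perfused flow (see above).

## Functiogram

Each voxel's regional flow (ml/100ml/min) is divided among 1.5·10⁹
sinusoids per 100 ml to set the per-sinusoid flow of an STU (pressure
rescaled at fixed geometry); the resulting ΔGlu_PV converts to a tissue
flux as flux (µmol/g/h) = flow · ΔGlu_PV · 60/100.  Voxel flows are
quantised (default 12 levels) so large maps need few unit solutions.
Because extraction grows as flow falls, the flux map's coefficient of
variation is below the flow map's — the variance damping seen when
comparing perfusion and metabolic heterogeneity.  The synthetic map
generator (truncated Gaussian, mean 44.3, SD 6.1 ml/100ml/min) stands in
for undeposited CT data; it reproduces first and second moments but none
of the spatial correlation of real perfusion maps, so map-level results
demonstrate the conversion pipeline, not regional anatomy.

## What the synthetic conditions do not show

The straight-tube unit ignores sinusoidal branching and anastomoses;
oxygen, amino-acid and lipid metabolism are outside the model (all
gluconeogenic precursors are lumped into "lactate"); adenine/pyridine
nucleotides are clamped, so energy-state feedback is absent; hormone
secretion dynamics and circadian glycogen effects are not modelled.
Passing tests on synthetic perfusion maps says nothing about real CT
data beyond the mean-flow conversion, and the glycogen zonation pattern
(periportal-dominant amplitude) reflects one of several contradictory
experimental reports.

## Numerical choices and degenerate inputs

Plasma glucose below 0.1 mM is rejected (uncalibrated regime); the
hormone curves warn outside 3–15 mM and extrapolate.  Glycogen is
bounded by the synthase capacity term (500 mM glucosyl units).  The
cellular Newton clips log-concentrations to [1e-12, 1e4] mM; steady-state
sweeps warm-start from the neighbouring glucose value.  Ties in the
functiogram's flow quantisation resolve by right-closed quantile bins.
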