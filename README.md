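# hepstu — a multiscale model of the hepatic sinusoidal tissue unit

The liver switches between producing and consuming glucose to hold plasma
glucose between ~3 and ~10 mM.  How well it does so depends on three
things at once: the metabolic capacity of hepatocytes, their zonated
enzyme endowment along the portal→central axis, and the microcirculation
that delivers substrates and hormones to them.  `hepstu` models the
smallest tissue element that contains all three — the **sinusoidal tissue
unit (STU)**: one sinusoid, its space of Disse, and the adjacent layer of
N hepatocytes — and integrates it up to organ scale.  It is written for
systems biologists and physiologists who want a mechanistic, runnable
account of hepatic glucose exchange, from single-enzyme kinetics to
CT-perfusion-derived flux maps.

## The model

* **Hepatocyte**: a kinetic ODE model of glycolysis, gluconeogenesis and
  glycogen turnover — 24 metabolites in cytosol/ER/mitochondrion, 32
  reactions and carriers (GK, GPI, PFK1, ALD, TPI, GAPDH, PGK, PGM, EN,
  PK, LDH, G6PP, PFK2/FBP2, FBP1, PEPCK, PC, MDH, PGM1, UGT, GP, GS,
  GLUT2, MCT, and the organelle transporters).  Insulin and glucagon act
  through the phosphorylated fraction γ ∈ [0,1] of the five
  interconvertible enzymes (GS, GP, PK, PFK2, FBP2).
* **Zonation**: enzyme abundance varies linearly along the axis,
  E(i) = E_PP·(1 + (i−1)/(N−1)·(α−1)), α = E_PC/E_PP, with the
  glycolytic limb pericentral (pyruvate kinase α = 3) and the
  gluconeogenic limb periportal.  The mean hepatocyte (MH) has
  Vmax = (V_PP + V_PC)/2.
* **Microcirculation**: Hagen–Poiseuille flow in the lumen and the Disse
  annulus, Starling filtration across the fenestrated endothelium,
  fenestral and axial diffusion, lymph drainage, and receptor-mediated
  hormone clearance at the cell surface.
* **The coupled unit**: with N = 20 hepatocytes the assembled system has
  889 ODEs.  Its tissue-scale output is the porto-venous glucose
  difference ΔGlu_PV = c_portal − c_venous (positive = net uptake); the
  **set-point** is the plasma glucose at which the net exchange flux is
  zero.

Experiment drivers cover set-point curves, indicator dilution (RBC,
albumin, labelled water), 48 h starvation–refeeding, Monte-Carlo
sampling of tissue variability, parameter sensitivities
S(p) = Δ(ΔGlu_PV)/(2ε·ΔGlu_PV), and the conversion of regional
blood-flow maps into maps of glucose exchange ("functiograms").
`docs/methods.md` documents every assumption, parameter and numerical
choice.

## Worked example

```sh
hepstu set-point --out results/
cat results/set_points.tsv
```

```
# experiment: set-point
# seed: 0
# units: set-point mM plasma glucose
# sign_conventions: positive glucose flux = hepatic uptake; ...
cell    set_point_mM
PPH     7.27587890625
MH      6.29150390625
PCH     5.58837890625
```

The periportal hepatocyte keeps producing glucose until plasma glucose
reaches ≈7.3 mM, the pericentral one switches to net uptake already at
≈5.6 mM — the zonated division of labour between gluconeogenic
(periportal) and glycolytic (pericentral) cells.  The whole unit's
set-point is *higher* than both (≈7.1 mM, `hepstu stu-steady`):
portal hormone levels are twice systemic and the liver strips insulin
much faster than glucagon, so hepatocytes inside the tissue see a more
glucagon-dominated signal than isolated cells at the same glucose.

The same library calls are available in Python:

```python
from hepstu import assemble_stu, steady_state_stu
r = steady_state_stu(assemble_stu(), portal_glucose=10.0)
print(r.delta_glu_pv)        # 2.667 mM net uptake at 10 mM portal
print(r.per_cell_gef)        # per-cell exchange flux, periportal first
```

At portal glucose between 6 and 8 mM the per-cell fluxes change sign
along the sinusoid: upstream cells release glucose that downstream cells
re-consume — an intra-sinusoidal glucose cycle.

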