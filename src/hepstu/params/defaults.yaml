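# Default run configuration.  Every run writes a resolved copy of this
# structure next to its outputs, so results are reproducible from the file.
model:
  # Vmax overrides of the mean hepatocyte, mM/min, e.g. {GK: 3.0}
  vmax: {}
  # zonation-ratio overrides, e.g. {PK: 2.5}
  alpha: {}
geometry:
  radius: 4.0          # um, sinusoid lumen radius
  length: 300.0        # um, sinusoid length (15 um per hepatocyte)
  disse: 1.5           # um, thickness of the space of Disse
  hepatocyte: 30.0     # um, thickness of the hepatocyte layer
  n_cells: 20
  fenestration: 0.07   # endothelial open-area fraction
systemic:
  preset: in_vivo      # in_vivo | perfused
  # explicit overrides of SystemicParams fields, e.g. {p_portal: 6.1}
  overrides: {}
hormones:
  # overrides of TransferFunctions fields, e.g. {clear_ins: 4.0e5}
  overrides: {}
dilution:
  # gamma-variate bolus approximating the measured red-cell arrival curve
  input_a: 2.0         # shape exponent
  input_b: 10.0        # s, decay scale
  t_max: 400.0         # s, simulated window
protocol:
  experiment: stu-steady
  portal_glucose: 7.5  # mM
  portal_lactate: 2.0  # mM
  glucose_grid: [3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
  tracer: water
  parameter: "vmax:PC" # sensitivity target
  epsilon: 0.05
  n_samples: 20        # Monte-Carlo repetitions
  map_shape: [4, 4, 2] # synthetic perfusion-map grid
  map_mean: 44.3       # ml/100ml/min
  map_sd: 6.1
output:
  directory: results
  format: tsv
seed: 0
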