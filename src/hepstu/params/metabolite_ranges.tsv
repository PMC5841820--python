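species	low_mM	high_mM	note
g6p	0.10	0.90	hepatic glucose-6-phosphate, freeze-clamp literature; synthetic compilation, not digitized figure data
f6p	0.03	0.30	equilibrium with Glc6P
f16bp	0.002	0.040	fructose-1,6-bisphosphate
dhap	0.02	0.30	dihydroxyacetone phosphate
grap	0.001	0.03	glyceraldehyde-3-phosphate
pg3	0.15	0.60	3-phosphoglycerate
pep	0.05	0.40	phosphoenolpyruvate
pyr	0.04	0.30	pyruvate
lac	0.5	3.5	lactate
mal	0.15	0.80	malate
oa	0.001	0.02	oxaloacetate
g1p	0.005	0.10	glucose-1-phosphate
udpg	0.10	0.60	UDP-glucose
f26bp	0.001	0.030	fructose-2,6-bisphosphate
glyc	20	450	glycogen (glucosyl units), fed-fasted span
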