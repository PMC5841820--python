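enzyme	alpha	sd	source
GK	1.26	0.15	pericentral enrichment of glucokinase, calibration within reported spread
PFK1	1.2	0.12	pericentral enrichment of phosphofructokinase-1, calibration within reported spread
PK	3.0	0.45	pyruvate kinase up to 3-fold higher pericentrally, isolated-cell assays
PFK2	1.3	0.15	bifunctional PFK2/FBP2 protein, pericentral enrichment
FBP2	1.3	0.15	bifunctional PFK2/FBP2 protein, pericentral enrichment
G6PP	0.88	0.08	periportal enrichment of glucose-6-phosphatase, calibration within reported spread
FBP1	0.90	0.08	periportal enrichment of fructose-1,6-bisphosphatase, calibration within reported spread
PEPCK	0.82	0.07	periportal enrichment of PEP carboxykinase, calibration within reported spread
PC	0.85	0.08	periportal enrichment of mitochondrial pyruvate carboxylase, calibration within reported spread
GS	0.90	0.08	periportal onset of glycogen synthesis, histochemistry literature
GP	0.92	0.08	periportal enrichment of glycogen phosphorylase, histochemistry literature
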