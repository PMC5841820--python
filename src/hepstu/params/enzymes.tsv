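reaction	parameter	value	unit	provenance
GK	Vmax	2.99	mM/min	calibrated to organ-scale glucose exchange
GK	h	1.7	-	hepatic glucokinase cooperativity, enzyme literature
GK	Kglc	8.0	mM	glucokinase S0.5, enzyme literature
GK	Kif6p	0.30	mM	GKRP-mediated Fru6P inhibition, effective
GPI	Vmax	65.0	mM/min	near-equilibrium enzyme, high capacity
GPI	Keq	0.29	-	equilibrium constant Glc6P<->Fru6P
GPI	Kg6p	0.40	mM	enzyme literature
GPI	Kf6p	0.12	mM	enzyme literature
PFK1	Vmax	1.3	mM/min	calibrated
PFK1	h	1.8	-	allosteric cooperativity
PFK1	Kf6p	1.30	mM	S0.5 without activator
PFK1	Kaf26bp	0.005	mM	Fru26P2 activation constant
PFK1	Katp	0.10	mM	enzyme literature
ALD	Vmax	26.0	mM/min	high-capacity step
ALD	Keq	0.069	mM	equilibrium constant (mM basis)
ALD	Kf16bp	0.012	mM	enzyme literature
ALD	Kdhap	0.35	mM	enzyme literature
ALD	Kgrap	0.08	mM	enzyme literature
TPI	Vmax	130.0	mM/min	near-equilibrium enzyme
TPI	Keq	0.045	-	DHAP->GraP equilibrium
TPI	Kdhap	0.59	mM	enzyme literature
TPI	Kgrap	0.40	mM	enzyme literature
GAPDH	Vmax	65.0	mM/min	high-capacity step
GAPDH	Keq0	0.00008	1/mM	chemical Keq before cofactor folding
GAPDH	Kgrap	0.08	mM	enzyme literature
GAPDH	Kbpg	0.008	mM	enzyme literature
PGK	Vmax	104.0	mM/min	near-equilibrium enzyme
PGK	Keq0	1750	-	chemical Keq before cofactor folding
PGK	Kbpg	0.002	mM	enzyme literature
PGK	Kpg3	0.60	mM	enzyme literature
PGM	Vmax	78.0	mM/min	near-equilibrium enzyme
PGM	Keq	0.15	-	3PG<->2PG equilibrium
PGM	Kpg3	0.50	mM	enzyme literature
PGM	Kpg2	0.08	mM	enzyme literature
EN	Vmax	78.0	mM/min	near-equilibrium enzyme
EN	Keq	4.6	-	2PG<->PEP equilibrium
EN	Kpg2	0.06	mM	enzyme literature
EN	Kpep	0.30	mM	enzyme literature
PK	Vmax	11.7	mM/min	calibrated
PK	h	3.0	-	allosteric cooperativity
PK	Kpep	0.80	mM	S0.5 of dephosphorylated form
PK	Kpep_p	2.50	mM	S0.5 of phosphorylated form
PK	Kaf16bp	0.010	mM	Fru16P2 activation constant
PK	Kadp	0.30	mM	enzyme literature
PK	rp	0.45	-	relative capacity of phosphorylated form
LDH	Vmax	26.0	mM/min	high-capacity step
LDH	Keq0	11100	-	chemical Keq before cofactor folding
LDH	Kpyr	0.14	mM	enzyme literature
LDH	Klac	8.0	mM	enzyme literature
G6PP	Vmax	3.51	mM/min	calibrated
G6PP	Km	2.0	mM	glucose-6-phosphatase Km
PFK2	Vmax	0.065	mM/min	calibrated
PFK2	Kf6p	0.032	mM	kinase limb Km
PFK2	Katp	0.15	mM	enzyme literature
PFK2	rp	0.12	-	residual activity of phosphorylated form
FBP2	Vmax	0.195	mM/min	calibrated
FBP2	Kf26bp	0.010	mM	phosphatase limb Km
FBP2	rp	0.12	-	residual activity of dephosphorylated form
FBP1	Vmax	1.56	mM/min	calibrated
FBP1	Kf16bp	0.010	mM	enzyme literature
FBP1	Kif26bp	0.004	mM	Fru26P2 inhibition constant
PEPCK	Vmax	3.25	mM/min	calibrated
PEPCK	Koa	0.010	mM	enzyme literature
PEPCK	Kgtp	0.06	mM	enzyme literature
PC	Vmax	4.16	mM/min	calibrated
PC	Kpyr	0.22	mM	enzyme literature
PC	Katp	0.22	mM	enzyme literature
PC	Kioa	0.02	mM	oxaloacetate product inhibition
NDK	Vmax	1.3	mM/min	housekeeping capacity
NDK	Keq	1.0	-	near-unity equilibrium
NDK	Katp	1.2	mM	enzyme literature
NDK	Kgdp	0.15	mM	enzyme literature
MDH	Vmax	26.0	mM/min	near-equilibrium enzyme
MDH	Keq0	0.000028	-	chemical Keq before cofactor folding
MDH	Kmal	0.80	mM	enzyme literature
MDH	Koa	0.04	mM	enzyme literature
MDHM	Vmax	26.0	mM/min	near-equilibrium enzyme
MDHM	Keq	200	-	apparent Keq folding mitochondrial redox state
MDHM	Koa	0.006	mM	enzyme literature
MDHM	Kmal	1.0	mM	enzyme literature
PPASE	Vmax	13.0	mM/min	housekeeping capacity
PPASE	Km	0.02	mM	enzyme literature
PGM1	Vmax	39.0	mM/min	near-equilibrium enzyme
PGM1	Keq	0.0588	-	Glc6P<->Glc1P equilibrium
PGM1	Kg6p	0.67	mM	enzyme literature
PGM1	Kg1p	0.045	mM	enzyme literature
UGT	Vmax	5.2	mM/min	calibrated
UGT	Kg1p	0.10	mM	enzyme literature
UGT	Kutp	0.25	mM	enzyme literature
UGT	Keq	1.0	-	uridylyltransferase equilibrium
UGT	Kudpg	0.35	mM	product binding
GP	Vmax	2.6	mM/min	calibrated
GP	rb	0.04	-	basal activity of dephosphorylated (b) form
GP	Kglyc	100	mM	glycogen half-saturation (glucosyl units)
GP	Kiglc	6.0	mM	glucose inhibition of the a form
GS	Vmax	1.95	mM/min	calibrated
GS	Kudpg	0.15	mM	a-form Km
GS	Kudpg_b	0.80	mM	b-form Km
GS	rb	0.25	-	relative capacity of b form
GS	Kag6p	0.45	mM	Glc6P activation of the b form
GS	capacity	500	mM	glycogen storage capacity (glucosyl units)
GLC6PT	Vmax	5.85	mM/min	calibrated
GLC6PT	Km	0.50	mM	transporter literature
GLCT	Vmax	65.0	mM/min	fast ER glucose export
GLCT	Km	15.0	mM	low-affinity facilitated transport
PYRT	Vmax	10.4	mM/min	mitochondrial pyruvate carrier capacity
PYRT	Km	0.30	mM	transporter literature
PEPT	Vmax	3.9	mM/min	adenine-nucleotide translocator-like capacity
PEPT	Km	0.30	mM	transporter literature
MALT	Vmax	13.0	mM/min	dicarboxylate carrier capacity
MALT	Km	0.71	mM	transporter literature
GLUT2	Vmax	39.0	mM/min	high-capacity low-affinity hepatocyte transport
GLUT2	Km	17.0	mM	GLUT2 Km
LACT	Vmax	13.0	mM/min	monocarboxylate transporter capacity
LACT	Km	3.0	mM	MCT Km
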