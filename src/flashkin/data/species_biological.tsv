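name	diffusion_1e-9_m2_s	initial_conc_M	clamped	boundary_clamped
e_aq	4.9	0	0	0
H	7.0	0	0	0
OH	2.2	0	0	0
H2	4.8	0	0	0
H2O2	2.3	0	0	0
O2	2.1	0	0	1
O2-	2.1	0	0	0
HO2	2.0	0	0	0
HO2-	2.0	0	0	0
OH-	5.3	1e-7	0	0
H+	9.46	1e-7	0	0
O-	2.0	0	0	0
H2O	0	55.3	1	0
RH	0	1.0	0	0
R	0	0	0	0
ROO	0	0	0	0
GSH	0	6.5e-3	0	0
lipid	0	1e-6	0	0
Fe2+	0	8.9e-7	1	0
catalase	0	8e-8	1	0
XSH	0	1.0	1	0
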