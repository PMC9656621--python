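id	reactant1	reactant2	products	k	k_units
1	e_aq	e_aq	H2;OH-;OH-	6.47e9	M-1s-1
2	H	H	H2	5.03e9	M-1s-1
3	OH	OH	H2O2	4.75e9	M-1s-1
4	e_aq	H	H2;OH-	2.65e10	M-1s-1
5	e_aq	OH	OH-	2.95e10	M-1s-1
6	H	OH	H2O	1.44e10	M-1s-1
7	e_aq	H2O2	OH;OH-	1.41e10	M-1s-1
8	e_aq	O2	O2-	1.90e10	M-1s-1
9	e_aq	O2-	OH-;HO2-	1.30e10	M-1s-1
10	e_aq	HO2	HO2-	2.00e10	M-1s-1
11	H	H2O2	OH;H2O	1.00e8	M-1s-1
12	H	O2	HO2	2.00e10	M-1s-1
13	H	HO2	H2O2	2.00e10	M-1s-1
14	H	O2-	HO2-	2.00e10	M-1s-1
15	OH	H2O2	HO2;H2O	2.30e7	M-1s-1
16	OH	O2-	O2;OH-	9.00e9	M-1s-1
17	OH	HO2	O2;H2O	1.00e10	M-1s-1
18	HO2	HO2	H2O2;O2	7.60e5	M-1s-1
19	HO2	O2-	H2O2;O2;OH-	1.14e8	M-1s-1
20	H+	OH-	H2O	1.00e11	M-1s-1
21	H2O		H+;OH-	1.29e-5	s-1
22	H+	HO2-	H2O2	2.00e10	M-1s-1
23	H2O2		H+;HO2-	6.49e-2	s-1
24	H2O2	OH-	HO2-;H2O	1.18e10	M-1s-1
25	HO2-	H2O	H2O2;OH-	9.97e5	M-1s-1
26	OH		H+;O-	6.49e-2	s-1
27	H+	O-	OH	4.52e10	M-1s-1
28	OH	OH-	O-;H2O	1.18e10	M-1s-1
29	O-	H2O	OH;OH-	9.97e5	M-1s-1
30	HO2		H+;O2-	6.62e5	s-1
31	H+	O2-	HO2	3.00e10	M-1s-1
32	HO2	OH-	O2-;H2O	9.78e-2	M-1s-1
33	O2-	H2O	HO2;OH-	1.18e10	M-1s-1
34	H+	e_aq	H	2.11e10	M-1s-1
35	H		H+;e_aq	3.7	s-1
36	H	OH-	e_aq;H2O	2.00e7	M-1s-1
37	e_aq	H2O	H;OH-	1.23e1	M-1s-1
38	H	H2O	H2;OH	2.26e-5	M-1s-1
39	H2	OH	H;H2O	4.50e7	M-1s-1
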