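# Reference fold changes and FDR (%) for the 69-gene top stem-cell
# signature, relative to the myoepithelial and the combined luminal
# populations (genes >2.5-fold up in stem cells against both, FDR <5%).
gene	fc_myo	fdr_myo_pct	fc_lum	fdr_lum_pct
4933439F18Rik	2.60	2.44	4.93	0
Adam12	5.40	2.45	2.77	0
Bcor	2.77	3.37	2.87	0
Bptf	3.98	3.49	7.57	0
Ccnd2	2.83	3.49	8.89	0
Cdk5rap2	2.64	0.58	3.33	0
Cdkl2	2.66	1.75	2.86	0
Col12a1	3.76	2.85	4.18	0
Col17a1	6.72	3.49	2.51	0
Col5a2	2.97	0.58	3.55	0
Dab2	3.53	3.49	2.51	0
Depdc6	2.63	2.25	3.88	0
Diap2	2.54	2.85	2.97	0
Dlc1	2.54	3.37	5.57	0
Dpysl3	2.68	3.49	4.92	0
Eif2ak2	2.75	2.85	2.83	0
Elk3	2.68	3.49	3.26	0
Erg	2.64	2.85	2.55	0
Fabp4	3.59	2.44	2.50	0
Filip1	2.55	4.30	2.68	0
Gfra2	3.21	0.37	10.55	0
Gltscr2	2.51	3.49	2.71	0
Gpatch4	2.63	3.90	3.28	0
Grik3	3.29	0.96	4.53	0
Gsn	2.73	2.44	2.98	0
Htr1d	2.78	2.02	5.85	0
Ift57	2.90	0.00	3.18	0
Kank2	3.19	1.59	4.23	0
Kif26b	4.02	0.00	3.64	0
Krt15	3.38	1.75	3.15	0
Lgals1	3.01	0.00	6.39	0
Lgr5	7.76	0.00	2.94	0
Ltbp2	2.87	0.00	6.94	0
Mllt3	2.88	2.06	5.10	0
Mme	3.17	1.59	4.29	0
Mtap1b	6.74	2.08	3.64	0
Mybl1	3.05	2.06	3.17	0
Nf2	3.14	3.37	3.46	0
Nfatc2	2.81	1.54	6.35	0
Ngfr	2.95	3.49	3.16	0
Nkain2	3.14	2.23	3.78	0
Nox4	5.04	0.58	2.69	0
Ogn	5.79	1.71	2.68	0
Pcdh7	2.68	3.49	5.51	0
Pdcd6ip	2.93	2.85	3.77	0
Plcb1	2.87	1.10	2.72	0
Ppp1r14a	2.61	3.49	3.14	0
Rarres2	2.90	2.06	2.87	0
Rpf2	3.95	4.30	3.36	3.98
Runx2	2.60	2.44	2.95	0
Samd4	4.94	1.75	5.49	0
Scaper	3.69	3.49	2.68	1.86
Scube3	3.71	0.58	4.39	0
Sfrp1	3.51	1.55	5.20	0
Sgcb	2.61	1.99	2.79	0
Sh3d19	2.94	2.44	5.46	0
Slc35f1	5.18	2.06	2.61	0
Slco2a1	3.38	2.08	4.18	0
Slu7	2.80	3.56	2.54	0
Stk39	3.20	3.49	4.15	0
Sync	2.58	2.44	3.86	0
Synpo2	3.56	1.59	4.10	0
Thsd7a	3.41	3.90	2.50	0
Tm6sf1	3.83	2.44	2.65	0
Tnc	21.41	0.00	2.65	0
Trak1	2.96	4.30	4.86	0
Vsnl1	5.30	0.00	5.35	0
Wipf1	2.75	0.58	3.98	0
Zfhx3	3.32	2.06	3.82	0
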