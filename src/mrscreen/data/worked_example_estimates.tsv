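exposure	level	method	or	ci_low	ci_high	pvalue
Enterobacteriales	order	IVW	1.37	1.07	1.74	0.012
Enterobacteriales	order	WM	1.36	1.01	1.85	0.046
Enterobacteriales	order	MR-Egger	0.49	0.13	1.81	0.336
Pasteurellales	order	IVW	1.12	1.01	1.25	0.039
Pasteurellales	order	WM	1.13	0.96	1.32	0.130
Pasteurellales	order	MR-Egger	1.18	0.92	1.53	0.2163
Enterobacteriaceae	family	IVW	1.37	1.07	1.74	0.012
Enterobacteriaceae	family	WM	1.36	1.00	1.86	0.051
Enterobacteriaceae	family	MR-Egger	0.49	0.13	1.81	0.336
Pasteurellaceae	family	IVW	1.12	1.01	1.25	0.039
Pasteurellaceae	family	WM	1.13	0.97	1.31	0.117
Pasteurellaceae	family	MR-Egger	1.18	0.92	1.53	0.216
Bacteroidales S24.7 group	family	IVW	1.16	1.01	1.33	0.042
Bacteroidales S24.7 group	family	WM	1.16	0.97	1.38	0.113
Bacteroidales S24.7 group	family	MR-Egger	1.12	0.64	1.97	0.702
Prevotella 7	genus	IVW	1.14	1.05	1.25	0.002
Prevotella 7	genus	WM	1.13	1.01	1.26	0.028
Prevotella 7	genus	MR-Egger	1.12	0.67	1.88	0.681
Lachnospiraceae UCG008	genus	IVW	1.19	1.04	1.38	0.014
Lachnospiraceae UCG008	genus	WM	1.20	1.02	1.42	0.032
Lachnospiraceae UCG008	genus	MR-Egger	1.24	0.53	2.89	0.633
Butyricicoccus	genus	IVW	0.82	0.68	0.98	0.030
Butyricicoccus	genus	WM	0.83	0.64	1.08	0.161
Butyricicoccus	genus	MR-Egger	0.85	0.60	1.20	0.384
Alistipes	genus	IVW	1.20	1.01	1.42	0.034
Alistipes	genus	WM	1.20	0.96	1.50	0.117
Alistipes	genus	MR-Egger	0.86	0.37	2.00	0.736
Ruminiclostridium 6	genus	IVW	0.86	0.74	0.99	0.038
Ruminiclostridium 6	genus	WM	0.88	0.72	1.08	0.211
Ruminiclostridium 6	genus	MR-Egger	0.89	0.60	1.30	0.548
Eisenbergiella	genus	IVW	1.12	1.00	1.25	0.046
Eisenbergiella	genus	WM	1.04	0.90	1.21	0.580
Eisenbergiella	genus	MR-Egger	1.52	0.63	3.63	0.372
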