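clade	n_mtdnas	subs_per_site	se_subs_per_site	T_ml_ka	dT_ml_ka	rho	sigma	T_rho_ka	dT_rho_ka	star_assumption
T1	64	0.00026	0.00005	12.5	2.3	3.656	0.340	11.6	1.1	no
T1a	28	0.00023	0.00003	11.2	1.6	3.214	0.413	10.2	1.3	no
T1b	12	0.00021	0.00005	10.2	2.3	3.083	0.571	9.8	1.8	no
T1b1	10	0.00019	0.00005	9.3	2.4	2.600	0.600	8.2	1.9	no
T1c	15	0.00026	0.00007	12.5	3.6	4.000	0.625	12.7	2.0	no
T1c1	11	0.00026	0.00006	12.5	2.8	4.272	0.787	13.6	2.5	no
T1c1a	5	0.00026	0.00013	12.5	6.3	3.600	1.296	11.4	4.1	no
T1c1a1	4	0.00010	0.00004	4.9	2.0	1.500	0.375	4.8	1.2	no
T1d	5	0.00019	0.00005	9.4	2.3	3.000	0.917	9.5	2.9	no
T1d1	3	0.00013	0.00005	6.3	2.2	2.000	0.816	6.3	2.6	yes
T1e	2	0.00013	0.00009	6.3	4.5	1.000	0.707	3.2	2.2	yes
T1f	2	0.00023	0.00005	11.0	2.4	5.500	1.658	17.4	5.3	no
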