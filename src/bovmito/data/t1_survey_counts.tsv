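continent	country	breed	T1a	T1b	T1c	T1d	T1e	T1f
Europe	Italy	Agerolese	4	0	0	0	0	0
Europe	Italy	Calvana	0	0	0	0	2	0
Europe	Italy	Chianina	9	4	0	0	6	0
Europe	Italy	Cinisara	10	2	1	0	0	0
Europe	Italy	Italian Brown	1	0	0	0	0	0
Europe	Italy	Italian Podolian	5	0	0	0	0	3
Europe	Italy	Italian Red Pied	0	1	0	0	0	0
Europe	Italy	Marchigiana	6	5	0	0	0	0
Europe	Italy	Maremmana	3	0	0	0	0	0
Europe	Italy	Modicana	1	0	0	0	0	0
Europe	Italy	Reggiana	2	0	0	0	0	0
Europe	Italy	Romagnola	8	0	1	0	0	0
Europe	France	Limousin	3	0	0	0	0	0
Europe	Portugal	Alentejana	0	0	2	0	0	0
Europe	Turkey	Grey Steppe	0	1	0	0	0	0
Africa	Egypt	Domiaty	2	2	3	1	0	0
Africa	Egypt	Khaleit	0	2	4	0	0	0
Africa	Egypt	Menofi	5	3	3	0	0	1
Africa	Ethiopia	Abigar	6	4	0	1	0	0
Africa	Ethiopia	Arsi	5	25	0	2	0	0
Africa	Ethiopia	Boran	8	22	0	5	0	0
Africa	Ethiopia	Guraghe	1	10	0	0	0	0
Africa	Ethiopia	Bark	3	8	0	0	0	0
Africa	Ethiopia	Horro	14	39	0	1	0	0
Africa	Ethiopia	Sheko	6	10	0	0	0	0
America	Mexico	Baja California Creole	0	0	1	0	0	0
America	Mexico	Chihuahua Creole	1	0	0	0	0	0
America	Paraguay	Pampa Chaqueño Creole	0	0	3	0	0	0
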