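species	population	n	S	nHap	Hd	pi	distribution	status
G. locusta	Falckenstein	28	35	22	0.986	0.005	native	non_invasive
G. locusta	Helgoland	24	23	11	0.862	0.006	native	non_invasive
G. locusta	Warnemünde	18	21	13	0.954	0.005	native	non_invasive
G. salinus	Falckenstein	11	13	7	0.873	0.007	native	non_invasive
G. salinus	Helgoland	15	26	6	0.762	0.010	native	non_invasive
G. salinus	Travemünde	14	23	9	0.835	0.012	native	non_invasive
G. salinus	Puck Bay	7	5	4	0.714	0.003	native	non_invasive
G. tigrinus	Travemünde	10	0	1	0.000	0.000	non_native	invasive
G. tigrinus	Liu	22	20	5	0.732	0.018	non_native	invasive
G. tigrinus	Pärnu	19	22	7	0.784	0.017	non_native	invasive
G. tigrinus	St.John	9	1	2	0.222	0.000	non_native	invasive
G. tigrinus	St.Lawrence	24	11	2	0.290	0.006	non_native	invasive
G. tigrinus	Huron	7	0	1	0.000	0.000	native	invasive
G. tigrinus	Berry creek	11	2	3	0.655	0.002	native	invasive
G. tigrinus	Delaware	6	11	3	0.600	0.007	native	invasive
G. tigrinus	Deemers Beach	19	8	2	0.491	0.008	native	invasive
G. tigrinus	Virginia	40	25	18	0.918	0.011	native	invasive
G. tigrinus	Hudson	25	1	2	0.080	0.000	non_native	invasive
G. tigrinus	Rhode Island	10	4	5	0.756	0.002	native	invasive
G. tigrinus	Chesapeake	12	5	2	0.409	0.004	native	invasive
G. tigrinus	Neuse	9	3	4	0.583	0.002	non_native	invasive
G. tigrinus	Turku	10	21	4	0.711	0.021	non_native	invasive
G. tigrinus	Vistula	10	19	2	0.200	0.007	non_native	invasive
G. tigrinus	Brody	9	21	4	0.806	0.020	non_native	invasive
G. tigrinus	Byton	9	20	3	0.722	0.022	non_native	invasive
G. tigrinus	Anleger	10	0	1	0.000	0.000	non_native	invasive
G. tigrinus	Dierhagen	10	20	3	0.733	0.021	non_native	invasive
G. tigrinus	Ruhr Metropolis	6	4	3	0.800	0.004	non_native	invasive
G. tigrinus	Werra	10	0	1	0.000	0.000	non_native	invasive
G. tigrinus	Gouwzee	10	5	2	0.200	0.002	non_native	invasive
G. tigrinus	Bann	9	9	3	0.556	0.007	non_native	invasive
G. tigrinus	Neagh	12	4	3	0.530	0.003	non_native	invasive
G. oceanicus	Geomar	14	2	2	0.143	0.001	native	non_invasive
G. oceanicus	Maine	12	3	3	0.621	0.003	native	non_invasive
G. oceanicus	Maine2	21	0	1	0.000	0.000	native	non_invasive
G. oceanicus	St.Lawrence	17	2	3	0.485	0.002	native	non_invasive
G. oceanicus	Sudurland	8	0	1	0.000	0.000	native	non_invasive
G. oceanicus	Poland	42	11	8	0.347	0.003	native	non_invasive
P. maeoticus	Bandar-e Anzali	29	6	6	0.374	0.001	native	invasive
P. maeoticus	Jafrud	22	6	6	0.411	0.001	native	invasive
P. maeoticus	Shafarud	22	13	11	0.714	0.003	native	invasive
P. maeoticus	Sulina1	7	7	7	1.000	0.005	native	invasive
P. maeoticus	Sulina2	8	6	6	0.929	0.003	native	invasive
P. maeoticus	Kazantip	5	16	5	1.000	0.016	native	invasive
P. maeoticus	Astara	9	63	9	1.000	0.048	native	invasive
P. maeoticus	Talesh	8	56	7	0.964	0.029	native	invasive
P. maeoticus	Gisoom	6	6	5	0.933	0.004	native	invasive
P. maeoticus	Bandar-e Anzali2	7	56	6	0.952	0.031	native	invasive
P. maeoticus	Kia	6	5	5	0.933	0.003	native	invasive
P. maeoticus	Motel	6	6	6	1.000	0.004	native	invasive
P. maeoticus	Noor	6	4	5	0.933	0.003	native	invasive
P. maeoticus	Mahmood	8	7	8	1.000	0.003	native	invasive
P. maeoticus	Khazar	8	53	6	0.893	0.027	native	invasive
G. zaddachi	Warnemünde	24	44	10	0.667	0.00692	native	non_invasive
G. zaddachi	Kronenloch	26	46	12	0.926	0.01542	native	non_invasive
G. zaddachi	United Kingdom	5	4	2	0.4	0.00272	native	non_invasive
O. crassus	Gisom	14	6	3	0.538	0.00392	native	invasive
O. crassus	Havigh	18	22	8	0.778	0.00858	native	invasive
O. crassus	Chaboksar	9	4	2	0.389	0.00274	native	invasive
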