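# AP2/ERF superfamily roster of Chinese jujube (Ziziphus jujuba)
classification	gene_name	gene_id	gene_length_bp	n_residues	n_introns
RAV family	ZjRAV1	Zj.jz017257006	903	300	0
RAV family	ZjRAV2	Zj.jz038651061	1008	335	0
RAV family	ZjRAV3	Zj.jz036113082	1119	372	0
RAV family	ZjRAV4	Zj.jz035205041	933	310	0
RAV family	ZjRAV5	Zj.jz000565044	1173	390	0
AP2 family	ZjAP2.1	Zj.jz019129042	2928	542	9
AP2 family	ZjAP2.2	Zj.jz041021015	2812	488	9
AP2 family	ZjAP2.3	Zj.jz040641029	3126	437	9
AP2 family	ZjAP2.4	Zj.jz042613003	3412	508	9
AP2 family	ZjAP2.5	Zj.jz004979039	2599	425	8
AP2 family	ZjAP2.6	Zj.jz034305007	4556	512	8
AP2 family	ZjAP2.7	Zj.jz031261085	3381	565	8
AP2 family	ZjAP2.8	Zj.jz014397087	3645	738	7
AP2 family	ZjAP2.9	Zj.jz036113025	2724	554	7
AP2 family	ZjAP2.10	Zj.jz005437099	3248	504	8
AP2 family	ZjAP2.11	Zj.jz000799113	3248	662	7
AP2 family	ZjAP2.12	Zj.jz037039128	3179	636	7
AP2 family	ZjAP2.13	Zj.jz017745018	3792	354	6
AP2 family	ZjAP2.14	Zj.jz013305004	1822	234	3
AP2 family	ZjAP2.15	Zj.jz016003110	2075	409	6
AP2 family	ZjAP2.16	Zj.jz040083020	2058	410	6
AP2 family	ZjAP2.17	Zj.jz003705057	6536	889	14
ERF subfamily	ZjERF1	Zj.jz005919063	840	279	0
ERF subfamily	ZjERF2	Zj.jz039715069	843	280	0
ERF subfamily	ZjERF3	Zj.jz016319010	882	293	0
ERF subfamily	ZjERF4	Zj.jz042921045	2692	356	1
ERF subfamily	ZjERF5	Zj.jz044841003	1176	391	0
ERF subfamily	ZjERF6	Zj.jz012195054	690	229	0
ERF subfamily	ZjERF7	Zj.jz040945007	1080	359	0
ERF subfamily	ZjERF8	Zj.jz000565087	1017	338	0
ERF subfamily	ZjERF9	Zj.jz028467003	1086	361	0
ERF subfamily	ZjERF10	Zj.jz022619084	990	329	0
ERF subfamily	ZjERF11	Zj.jz025457076	1071	356	0
ERF subfamily	ZjERF12	Zj.jz036789017	1110	369	0
ERF subfamily	ZjERF13	Zj.jz044709040	921	306	0
ERF subfamily	ZjERF14	Zj.jz007373046	714	237	0
ERF subfamily	ZjERF15	Zj.jz007373047	756	251	0
ERF subfamily	ZjERF16	Zj.jz007373045	660	219	0
ERF subfamily	ZjERF17	Zj.jz017087093	738	245	0
ERF subfamily	ZjERF18	Zj.jz044705014	901	201	0
ERF subfamily	ZjERF19	Zj.jz024825029	1014	337	0
ERF subfamily	ZjERF20	Zj.jz023977006	1101	366	0
ERF subfamily	ZjERF21	Zj.jz014121054	648	215	0
ERF subfamily	ZjERF22	Zj.jz039613031	720	239	0
ERF subfamily	ZjERF23	Zj.jz002027043	717	238	0
ERF subfamily	ZjERF24	Zj.jz000419014	711	236	0
ERF subfamily	ZjERF25	Zj.jz022243025	744	247	0
ERF subfamily	ZjERF26	Zj.jz044531028	693	230	0
ERF subfamily	ZjERF27	Zj.jz044531027	960	319	0
ERF subfamily	ZjERF28	Zj.jz042635003	1071	356	0
ERF subfamily	ZjERF29	Zj.jz044537207	663	220	0
ERF subfamily	ZjERF30	Zj.jz044537206	705	234	0
ERF subfamily	ZjERF31	Zj.jz044537208	789	262	0
ERF subfamily	ZjERF32	Zj.jz044537209	804	267	0
ERF subfamily	ZjERF33	Zj.jz042635005	816	271	0
ERF subfamily	ZjERF34	Zj.jz044531026	837	278	0
ERF subfamily	ZjERF35	Zj.jz024825042	681	226	0
ERF subfamily	ZjERF36	Zj.jz039613028	507	168	0
ERF subfamily	ZjERF37	Zj.jz005267064	525	174	0
ERF subfamily	ZjERF38	Zj.jz005267065	789	262	0
ERF subfamily	ZjERF39	Zj.jz026341063	579	192	0
ERF subfamily	ZjERF40	Zj.jz041523053	849	282	0
ERF subfamily	ZjERF41	Zj.jz019129098	675	224	0
ERF subfamily	ZjERF42	Zj.jz042905025	1907	447	1
ERF subfamily	ZjERF43	Zj.jz036649007	1368	381	1
ERF subfamily	ZjERF44	Zj.jz044705012	423	140	0
ERF subfamily	ZjERF45	Zj.jz007373041	405	134	0
ERF subfamily	ZjERF46	Zj.jz007373043	411	136	0
ERF subfamily	ZjERF47	Zj.jz044705013	435	144	0
ERF subfamily	ZjERF48	Zj.jz007373042	426	141	0
ERF subfamily	ZjERF49	Zj.jz219482001	426	141	0
ERF subfamily	ZjERF50	Zj.jz007373044	411	136	0
ERF subfamily	ZjERF51	Zj.jz218390001	411	136	0
ERF subfamily	ZjERF52	Zj.jz034557065	1361	300	1
ERF subfamily	ZjERF53	Zj.jz042733004	2568	384	1
ERF subfamily	ZjERF54	Zj.jz001627224	1076	325	1
ERF subfamily	ZjERF55	Zj.jz021445133	1344	447	0
ERF subfamily	ZjERF56	Zj.jz043265028	630	209	0
ERF subfamily	ZjERF57	Zj.jz008787065	930	309	0
DREB Subfamily	ZjDREB1	Zj.jz044537132	618	205	0
DREB Subfamily	ZjDREB2	Zj.jz043343275	690	229	0
DREB Subfamily	ZjDREB3	Zj.jz022481142	636	211	0
DREB Subfamily	ZjDREB4	Zj.jz041937025	669	222	0
DREB Subfamily	ZjDREB5	Zj.jz044811087	696	231	0
DREB Subfamily	ZjDREB6	Zj.jz043343280	651	216	0
DREB Subfamily	ZjDREB7	Zj.jz022481141	798	265	0
DREB Subfamily	ZjDREB8	Zj.jz043509016	609	202	0
DREB Subfamily	ZjDREB9	Zj.jz004979207	930	309	0
DREB Subfamily	ZjDREB10	Zj.jz029983048	777	258	0
DREB Subfamily	ZjDREB11	Zj.jz010621056	762	253	0
DREB Subfamily	ZjDREB12	Zj.jz012385028	741	246	0
DREB Subfamily	ZjDREB13	Zj.jz039389019	795	264	0
DREB Subfamily	ZjDREB14	Zj.jz032441015	567	188	0
DREB Subfamily	ZjDREB15	Zj.jz032441018	555	184	0
DREB Subfamily	ZjDREB16	Zj.jz032441019	570	189	0
DREB Subfamily	ZjDREB17	Zj.jz001229020	1263	420	0
DREB Subfamily	ZjDREB18	Zj.jz019129038	513	170	0
DREB Subfamily	ZjDREB19	Zj.jz019851111	722	198	1
DREB Subfamily	ZjDREB20	Zj.jz008787054	827	195	1
DREB Subfamily	ZjDREB21	Zj.jz025457028	978	325	0
DREB Subfamily	ZjDREB22	Zj.jz018471004	1164	387	0
DREB Subfamily	ZjDREB23	Zj.jz003705080	879	292	0
DREB Subfamily	ZjDREB24	Zj.jz013215045	1086	361	0
DREB Subfamily	ZjDREB25	Zj.jz025819289	1337	362	1
DREB Subfamily	ZjDREB26	Zj.jz013215010	1209	402	0
DREB Subfamily	ZjDREB27	Zj.jz041065010	570	189	0
DREB Subfamily	ZjDREB28	Zj.jz002027059	588	195	0
DREB Subfamily	ZjDREB29	Zj.jz041429113	777	258	0
DREB Subfamily	ZjDREB30	Zj.jz017087018	612	203	0
DREB Subfamily	ZjDREB31	Zj.jz023353019	1158	385	0
DREB Subfamily	ZjDREB32	Zj.jz002027126	1404	467	0
DREB Subfamily	ZjDREB33	Zj.jz034489035	680	189	1
DREB Subfamily	ZjDREB34	Zj.jz006119209	492	163	0
DREB Subfamily	ZjDREB35	Zj.jz032441029	471	156	0
DREB Subfamily	ZjDREB36	Zj.jz028857050	741	246	0
DREB Subfamily	ZjDREB37	Zj.jz017079070	615	204	0
DREB Subfamily	ZjDREB38	Zj.jz008869142	654	217	0
DREB Subfamily	ZjDREB39	Zj.jz017079071	402	133	0
Soloist	ZjERF.SOLOIST	Zj.jz031429031	3663	235	5
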