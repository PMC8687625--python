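ingredient_id	name	herbs	caco2	dl	literature_flag	concentration	conc_unit
MOL000006	Luteolin		0.19	0.25	false	—	—
MOL000008	Apigenin		0.43	0.21	false	—	—
MOL000012	Arachic acid		1.18	0.19	false	—	—
MOL000098	Quercetin		0.05	0.28	false	—	—
MOL000105	Protocatechuic acid		0.10	0.04	true	—	—
MOL000223	Caffeic acid		0.21	0.05	true	—	—
MOL000286	beta-Amyrin acetate		1.42	0.74	false	—	—
MOL000357	Sitogluside		-0.14	0.62	false	—	—
MOL000389	Ferulic acid (CIS)		0.53	0.06	true	—	—
MOL000476	Physcion		0.52	0.27	false	—	—
MOL000874	Paeonol		0.93	0.04	true	—	—
MOL001399	TWT		1.85	0.18	false	—	—
MOL001494	Mandenol		1.46	0.19	false	—	—
MOL001729	Crysophanol		0.62	0.21	false	—	—
MOL001838	Dipalmitin		0.39	0.44	false	—	—
MOL002008	Myricetin		-0.15	0.31	false	—	—
MOL002140	Perlolyrine		0.88	0.27	false	—	—
MOL002141	PLO		0.69	0.43	false	—	—
MOL002677	L-1,2-Dipalmitin		0.38	0.49	false	—	—
MOL002684	gamma-Tocotrienol		1.55	0.53	false	—	—
MOL002687	Guanosine		-1.21	0.21	true	—	—
MOL002695	Lignan		0.42	0.65	false	—	—
MOL002696	Lirioresinol A		0.41	0.67	false	—	—
MOL002706	Phytoene		2.22	0.5	false	—	—
MOL002712	6-Hydroxykaempferol		0.16	0.27	false	—	—
MOL002714	Baicalein		0.63	0.21	false	—	—
MOL002759	Glyceryl pps		0.45	0.35	false	—	—
MOL002764	MEGxp0_000365		-0.12	0.53	false	—	—
MOL002771	VIV		1.70	0.55	false	—	—
MOL002883	Ethyl oleate (NF)		1.40	0.19	false	—	—
MOL004495	Tigogenin		0.87	0.81	false	—	—
MOL005043	Campest-5-en-3beta-ol		1.32	0.71	false	—	—
MOL005368	Methyl tricosanoate		1.43	0.33	false	—	—
MOL006452	1,5-Dihydroxy-3-methylanthraquinone		0.56	0.21	false	—	—
MOL006992	(2R,3R)-4-Methoxyl-distylin		0.17	0.30	false	—	—
MOL006999	Stigmast-7-en-3-ol		1.32	0.75	false	—	—
MOL007006	Oxypaeoniflorin		-1.91	0.78	true	—	—
MOL007022	Evofolin B		0	0.22	false	—	—
MOL007050	2-(4-hydroxy-3-methoxyphenyl)-5-(3-hydroxypropyl)-7-methoxy-3-benzofurancarboxaldehyde		0.35	0.40	false	—	—
MOL007068	Przewaquinone B		0.39	0.41	false	—	—
MOL007074	Salvianolic acid B		-1.67	0.41	true	—	—
MOL007092	Dan-shexinkum c		0.75	0.21	false	—	—
MOL007110	Isotanshinone IIb		0.38	0.45	false	—	—
MOL007111	Isotanshinone II		1.03	0.40	false	—	—
MOL007116	Methylrosmarinate		0	0.37	false	—	—
MOL007117	Methyltanshinonate		0.56	0.55	false	—	—
MOL007130	Prolithospermic acid		0.10	0.31	false	—	—
MOL007132	(2R)-3-(3,4-dihydroxyphenyl)-2-[(Z)-3-(3,4-dihydroxyphenyl)acryloyl]oxy-propionic acid		-0.33	0.35	false	—	—
MOL007134	Danshensu		-0.27	0.06	true	—	—
MOL007145	Salviolone		1.04	0.24	false	—	—
MOL007151	Tanshindiol B		0.05	0.45	false	—	—
MOL007154	Tanshinone IIa		1.05	0.40	false	—	—
MOL008278	4-chloro-N-[1-methyl-5-[[1-methyl-5-[[1-methyl-5-(2-morpholinoethylcarbamoyl)pyrrol-3-yl]carbamoyl]pyrrol-3-yl]carbamoyl]pyrrol-3-yl]-5-[2-(2-pyridyl)ethylamino]isothiazole-3-carboxamide		-0.21	0.31	false	—	—
COM10	Ethyl ferulate		—	—	true	—	—
COM11	Gallic acid		—	—	true	—	—
COM12	Galuteolin		—	—	true	—	—
COM14	Hyperoside		—	—	true	—	—
COM16	Protocatechuic aldehyde		—	—	true	—	—
COM17	Rosmarinic acid		—	—	true	—	—
COM23	Uridine		—	—	true	—	—
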