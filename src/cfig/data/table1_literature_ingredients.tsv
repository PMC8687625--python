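ingredient_id	name	herbs	caco2	dl	literature_flag	concentration	conc_unit
COM1	4',5,6,7-Tetrahydroxyflavanone 6,7-di-O-b-D-glucopyranoside		—	—	true	—	—
COM2	5-Hydroxymethylfurfural		—	—	true	10.38	ug/ml
COM3	6-Hydroxykaemferol 3,6,7-tri-O-b-D-glucopyranoside		—	—	true	—	—
COM4	6-Hydroxykaemferol 3,6-di-O-b-Dglucopyranosyl-7-O-b-Dglucuronopyranoside		—	—	true	—	—
COM5	Anhydrosafflor yellow B		—	—	true	—	—
COM6	Benzoylpaeoniflorin		—	—	true	39.82	ug/ml
COM7	Butylidenephthalide		—	—	true	0.02	ug/ml
COM8	Catechinic acid		—	—	true	5.76	ug/ml
COM9	Chlorogenic Acid		—	—	true	3.92	ug/ml
COM10	Ethyl ferulate		—	—	true	0.19	ug/ml
COM11	Gallic acid		—	—	true	6.60	ug/ml
COM12	Galuteolin		—	—	true	1.10	ug/ml
COM13	Hydroxysafflor yellow A		—	—	true	479.45	ug/ml
COM14	Hyperoside		—	—	true	0.63	ug/ml
COM15	Naringenin		—	—	true	0.35	ug/ml
COM16	Protocatechuic aldehyde		—	—	true	7.28	mg/L
COM17	Rosmarinic acid		—	—	true	5.07	ug/ml
COM18	Safflor yellow A		—	—	true	48.79	mg/L
COM19	Senkyunolide H		—	—	true	19.48	mg/L
COM20	Senkyunolide I		—	—	true	53.89	mg/L
COM21	Sodium Danshensu		—	—	true	0.49	ug/ml
COM22	Tanshinone IIA		—	—	true	0.10	ug/ml
COM23	Uridine		—	—	true	38.61	mg/L
MOL000105	Protocatechuic acid		0.10	0.04	true	4.81	ug/ml
MOL000223	Caffeic acid		0.21	0.05	true	5.25	ug/ml
MOL000389	Ferulic acid (CIS)		0.53	0.06	true	35.12	ug/ml
MOL000415	Rutin		—	—	true	2.27	ug/ml
MOL000874	Paeonol		0.93	0.04	true	0.03	ug/ml
MOL001924	Paeoniflorin		—	—	true	1963.86	mg/L
MOL001932	Galloylpaeoniflorin		—	—	true	—	—
MOL002687	Guanosine		-1.21	0.21	true	27.15	mg/L
MOL007004	Albiflorin		—	—	true	26.24	ug/ml
MOL007006	Oxypaeoniflorin		-1.91	0.78	true	40.54	ug/ml
MOL007074	Salvianolic acid B		-1.67	0.41	true	2.14	ug/ml
MOL007134	Danshensu		-0.27	0.06	true	48.49	mg/L
MOL007136	Salvianolic acid A		—	—	true	0.04	ug/ml
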