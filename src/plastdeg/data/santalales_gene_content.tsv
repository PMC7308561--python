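species	lifeform	total_genes	functional_genes	protein_coding	trna	rrna	deleted	pseudogenes
Erythropalum scandens	Autotroph	113	113	79	30	4	0	0
Osyris alba	FH	110	101	67	30	4	3	9
Osyris wightiana	FH	110	101	67	30	4	3	9
Santalum album	FH	108	101	67	30	4	5	7
Champereia manillana	FH	105	100	66	30	4	8	5
Dendrotrophe varians	OH	105	101	67	30	4	8	4
Ximenia americana	FH	103	102	68	30	4	10	1
Pyrularia edulis	FH	102	100	67	29	4	11	2
Schoepfia fragrans	FH	101	101	68	29	4	12	0
Schoepfia jasminodora	FH	101	101	68	29	4	12	0
Viscum yunnanense	OH	101	97	64	29	4	12	4
Viscum minimum	OH	100	98	66	28	4	13	2
Viscum album	OH	100	97	65	28	4	13	3
Viscum coloratum	OH	100	96	64	28	4	13	4
Viscum liquidambaricolum	OH	100	97	65	28	4	13	3
Viscum ovalifolium	OH	100	97	65	28	4	13	3
Viscum crassulae	OH	99	98	66	28	4	14	1
Pyrularia sinensis	FH	97	94	62	28	4	16	3
Taxillus sutchuenensis	OH	96	94	63	27	4	17	2
Scurrula notothixoides	OH	96	91	60	27	4	17	5
Macrosolen sp.	OH	96	94	63	27	4	17	2
Macrosolen tricolor	OH	96	95	64	27	4	17	1
Taxillus chinensis	OH	95	94	63	27	4	18	1
Scurrula parasitica	OH	95	94	63	27	4	18	1
Tolypanthus maclurei	OH	94	93	64	25	4	19	1
Dendrophthoe pentandra	OH	94	92	63	25	4	19	2
Loranthus tanakae	OH	94	90	61	25	4	19	4
Taxillus nigrans	OH	94	92	62	26	4	19	2
Helixanthera parasitica	OH	93	92	63	25	4	20	1
Malania oleifera	FH	85	84	58	22	4	28	1
Arceuthobium sichuanense	OH	84	81	54	23	4	29	3
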