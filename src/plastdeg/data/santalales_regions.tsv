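species	lifeform	total_bp	total_gc	lsc_bp	lsc_gc	ir_bp	ir_gc	ssc_bp	ssc_gc	coding_bp	coding_gc	noncoding_bp	noncoding_gc
Arceuthobium sichuanense	OH	107526	34.9	65171	30.1	21045	42.3	265	26.4	57987	40.0	49539	28.8
Schoepfia jasminodora	FH	118743	38.1	84168	36.1	12406	47.9	9763	30.7	70052	40.8	48691	34.3
Schoepfia fragrans	FH	120188	38.1	85643	36.1	12381	47.9	9783	30.6	70089	40.7	50099	34.4
Taxillus chinensis	OH	121363	37.3	70357	34.7	22462	43.0	6082	26.2	75421	39.6	45942	33.5
Taxillus nigrans	OH	121419	37.4	70181	34.8	22569	43.0	6100	26.2	74727	39.7	46692	33.8
Scurrula parasitica	OH	121750	37.2	70270	34.5	22687	42.9	6106	25.9	75603	39.6	46147	33.4
Dendrophthoe pentandra	OH	122451	36.3	72451	33.6	22118	42.2	5764	25.0	70262	40.3	52189	30.9
Taxillus sutchuenensis	OH	122562	37.3	70630	34.7	22915	42.8	6102	26.2	75292	39.7	47270	33.6
Loranthus tanakae	OH	123397	36.9	69522	34.8	23076	42.2	7723	24.4	69905	40.6	53492	32.1
Tolypanthus maclurei	OH	123581	36.8	72952	34.3	22185	42.4	6259	26.0	75765	39.6	47816	32.3
Scurrula notothixoides	OH	123810	37.3	71448	34.7	23101	42.9	6160	26.4	52652	41.8	71158	34.1
Helixanthera parasitica	OH	124881	36.5	73043	33.8	22752	42.3	6334	25.5	75359	39.4	49522	32.1
Malania oleifera	FH	125050	38.2	76387	35.0	24324	43.2	15	40.0	68012	41.5	57038	34.2
Viscum crassulae	OH	126064	36.4	73226	33.6	22105	43.4	8628	24.0	78219	39.3	47845	31.5
Macrosolen tricolor	OH	126617	37.6	71893	35.2	24702	42.4	5320	25.8	76219	40.0	50398	34.0
Macrosolen sp.	OH	128459	37.3	73347	34.8	22960	43.3	9192	27.3	70900	40.9	57559	32.9
Viscum liquidambaricolum	OH	128601	36.1	73831	33.1	23041	43.2	8688	23.7	77414	39.5	51187	30.8
Viscum coloratum	OH	128746	36.3	73686	33.4	23215	43.1	8630	24.3	76295	39.8	52451	31.1
Viscum album	OH	128921	36.4	73893	33.5	23198	43.2	8632	24.8	76120	39.9	52801	31.3
Viscum ovalifolium	OH	129465	36.1	74348	33.2	23203	43.1	8711	24.2	76210	39.9	53255	30.8
Pyrularia sinensis	FH	130015	37.3	83917	35.0	19316	40.7	7466	46.3	67533	41.0	62482	33.3
Viscum yunnanense	OH	130721	35.8	75844	32.8	22894	43.3	9089	22.6	70452	40.8	60269	30.2
Viscum minimum	OH	131016	36.2	75814	33.3	23094	43.2	9014	24.2	78115	39.6	52901	31.1
Pyrularia edulis	FH	132808	38.3	74811	36.1	24548	42.8	8901	31.2	76747	40.9	56061	34.6
Dendrotrophe varians	OH	140666	37.8	81684	35.5	24056	43.7	10870	29.7	76484	40.7	64182	34.4
Santalum album	FH	144101	38.0	83802	35.9	24511	43.1	11277	31.4	78274	40.8	65827	34.7
Osyris alba	FH	147253	37.7	84601	35.6	24340	43.1	13972	31.2	78206	40.7	69047	34.2
Champereia manillana	FH	147461	37.4	83505	35.3	28075	41.9	7806	27.9	78095	40.5	69366	33.9
Osyris wightiana	FH	147544	37.6	84569	35.5	24447	43.0	14081	31.1	78173	40.6	69371	34.2
Erythropalum scandens	Autotroph	156154	38.0	84799	36.2	26394	42.8	18567	32.3	90488	40.3	65666	34.8
Ximenia americana	FH	156834	36.8	87816	34.4	32691	40.4	3636	27.5	84385	40.0	72449	33.0
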