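order	species	total_len	lsc_len	ssc_len	repeat_len	total_genes	protein_genes	protein_dup	rrna_genes	rrna_dup	trna_genes	trna_dup	orientation	gc_percent	accession
Lycopodiales	Huperzia lucidula	154373	104088	19657	15314	124	85	0	4	4	27	4	IR	36.25	NC_006861.1
Lycopodiales	Huperzia serrata	154176	104080	19658	15219	130	85	2	4	4	30	5	IR	36.28	NC_033874.1
Isoetales	Isoetes flaccida	145303	91862	27205	13118	128	82	1	4	4	32	5	IR	37.94	GU191333.1
Selaginellales	Selaginella lyallii	110411	44943	45276	10096	83	60	1	4	4	12	2	DR	50.75	NC_041556.1
Selaginellales	Selaginella kraussiana	129971	46049	54728	14597	92	70	3	4	4	10	1	DR	52.33	NC_040926.1
Selaginellales	Selaginella remotifolia	131867	46351	55844	14836	95	70	3	4	4	12	2	DR	56.49	NC_041644.1
Selaginellales	Selaginella indica	122460	45711	48395	14177	86	61	3	4	4	12	2	DR	53.55	MK156801.1
Selaginellales	Selaginella vardei	121254	45792	47676	13893	84	61	3	4	4	10	2	DR	53.21	MG272482.1
Selaginellales	Selaginella lepidophylla	114693	80625	19452	7308	85	64	0	4	4	12	1	IR	51.94	NC_040927.1
Selaginellales	Selaginella sanguinolenta	147148	54436	59650	16531	102	67	2	4	4	22	3	DR	50.78	NC_041645.1
Selaginellales	Selaginella stauntoniana	126762	54231	47745	12393	76	60	1	4	4	6	1	DR	54.06	MK460598
Selaginellales	Selaginella tamariscina	126385	53219	47600	12783	75	59	1	4	4	6	1	DR	53.98	MK460597
Selaginellales	Selaginella doederleinii	142752	57841	62865	11023	100	75	1	4	4	14	2	DR	51.13	NC_041641.1
Selaginellales	Selaginella involvens	143192	58193	61075	11962	102	75	1	4	4	14	4	DR	50.82	MK460599
Selaginellales	Selaginella moellendorffii	143525	58198	61129	12099	99	75	1	4	4	12	3	DR	51.00	MG272484.1
Selaginellales	Selaginella bisulcata	140509	55598	59659	12626	85	59	3	4	4	12	3	DR	52.77	NC_041640.1
Selaginellales	Selaginella pennata	138024	54979	59847	11599	93	71	3	4	4	9	2	DR	52.91	NC_041643.1
Selaginellales	Selaginella hainanensis	144201	77780	40819	12801	103	77	3	4	4	12	3	IR	54.83	NC_041642.1
Selaginellales	Selaginella uncinata	144170	77706	40886	12789	101	75	3	4	4	11	4	IR	54.85	AB197035.2
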