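# Conserved mature miRNA variants of Pleopeltis minima, transcribed from the published table.
# The printed "6e10-4" E-values are stored as 6e-4. Reference ids keep the printed
# space-separated arm dialect. Read counts and E-values are as-printed annotation,
# re-echoed (never recomputed) by the loaders.
family	given_name	sequence	length_nt	total_reads	reference_mirna	blast_evalue
miR156	pmi-miR156_v1	TTGACAGAAGATAGAGAGCAC	21	1898	ath-miR157a 5p	0.002
miR156	pmi-miR156_v2	TGACAGAAGATAGAGAGCAC	20	225	ath-miR157d 5p	0.004
miR156	pmi-miR156_v3	TGACAGAAGATAGAGAGCACTT	22	14	ath-miR157a 5p	0.004
miR159	pmi-miR159_v1	TTTGGATTGAAGGGAGCTCTA	21	38	ath-miR159a 3p	0.002
miR159	pmi-miR159_v2	TTTGGATTGAAGGGAGCTCC	20	29	ath-miR159c 3p	0.004
miR160	pmi-miR160_v1	TTGCCTGGCTCCCTGCATGCC	21	23027	nta-miR160d 5p	0.004
miR160	pmi-miR160_v2	TTGCCTGGCTCCCTGCATGCA	21	353	nta-miR160d 5p	0.004
miR160	pmi-miR160_v3	TGCCTGGCTCCCTGCATGCCA	21	278	nta-miR160d 5p	0.002
miR162	pmi-miR162_v1	GGAGGCAGCGGTTCATCGATC	21	2	aly-miR162a 5p	0.002
miR162	pmi-miR162_v2	TCGATAAACCTCTGCATCCAG	21	2	aly-miR162a 3p	0.002
miR166	pmi-miR166_v1	TCGGACCAGGCTTCATTCCCC	21	290254	aly-miR166a 3p	0.002
miR166	pmi-miR166_v2	TCGGACCAGGCTTCATTCCCT	21	16666	osa-miR166m 3p	0.002
miR166	pmi-miR166_v3	TCGGACCAGGCTTCATTCCCA	21	1187	aly-miR166b 3p	0.004
miR166	pmi-miR166_v4	TCGGACCAGGCTTCATTCTT	20	298	cme-miR166i 3p	0.011
miR166	pmi-miR166_v5	TCGGACCAGGCTTCATCCCCC	21	186	ath-miR165a 3p	0.002
miR166	pmi-miR166_v6	TCGGACCAGGCTTCATTCCCCC	22	53	hbr-miR166b 3p	6e-4
miR166	pmi-miR166_v7	TCGGACCAGGCTTCATTGCCT	21	20	aly-miR166d 3p	0.008
miR167	pmi-miR167_v1	TGAAGCTGCCAGCATGATCTGA	22	6	bdi-miR167d 5p	6e-4
miR167	pmi-miR167_v2	TGAAGCTGCCAGCATGATCTGG	22	3	ath-miR167d 5p	6e-4
miR167	pmi-miR167_v3	TGAAGCTGCCAGCATGATCTGC	22	2	ata-miR167c 5p	6e-4
miR168	pmi-miR168_v1	TCGCTTGGTGCAGGTCGGGAA	21	133	ath-miR168a 5p	0.002
miR168	pmi-miR168_v2	TCGATTGGTGCAGATCGGGA	20	15	osa-miR168a 5p	0.024
miR169	pmi-miR169_v2	GGCAAGTGGTCCTTGGCTACCT	22	25	ath-miR169a 3p	0.024
miR169	pmi-miR169_v1	CGGCAAGTTGTCCCTGGCTAC	21	19	ath-miR169a 3p	0.022
miR171	pmi-miR171_v1	TTGAGCCGTGCCAATATCACAT	22	440	smo-miR171b 3p	0.002
miR172	pmi-miR172_v1	CGAGAATCTTGATGATGCTGC	21	653	vvi-miR172d 3p	0.004
miR172	pmi-miR172_v2	CGAGAATCCTGATGATGCTGC	21	335	mtr-miR172a 3p	0.01
miR172	pmi-miR172_v3	TGAGAATCTTGATGATGCTGC	21	64	vvi-miR172d 3p	0.002
miR172	pmi-miR172_v4	GGAATCTTGATGATGCTGCAA	21	19	ath-miR172e 3p	0.004
miR172	pmi-miR172_v5	TGCAGCACCATCAAGATTCAC	21	25	aly-miR172b 5p	0.004
miR319	pmi-miR319_v1	CTTGGACTGAAGGGAGCTCCC	21	1972	ppt-miR319d 3p	0.002
miR319	pmi-miR319_v2	TTGGACTGAAGGGAGCTCCT	20	1445	ath-miR319c 3p	0.004
miR319	pmi-miR319_v3	CTTGGACTGAAGGGAGCTCCT	21	113	mes-miR319h 3p	0.002
miR390	pmi-miR390_v1	AAGCTCAGGAGGGATAGCGCC	21	9170	ath-miR390a 5p	0.002
miR390	pmi-miR390_v2	AAGCTCAGGAGGGATAGCGCCT	22	489	ath-miR390a 5p	0.002
miR390	pmi-miR390_v3	AAGCTCAGGAGGGATAGCGCTT	22	15	ath-miR390a 5p	0.004
miR390	pmi-miR390_v4	CGCTATCTATCCTGAGTTTCA	21	1	ath-miR390a 3p	0.008
miR395	pmi-miR395_v1	CTGAAGTGTTTGGGGGAACTCT	22	2	aly-miR395e 3p	0.002
miR395	pmi-miR395_v2	CTGAAGTGTTTGGGGGAACTC	21	1	aly-miR395e 3p	0.002
miR395	pmi-miR395_v3	GTTCCTCTGAACACTTCATT	20	1	aly-miR395e 5p	0.024
miR396	pmi-miR396_v1	CTCAAGAAAGCTGTGGGAAAA	21	414	ath-miR396b 3p	0.004
miR396	pmi-miR396_v2	TTCCACAGCTTTCTTGAACTG	21	145	ath-miR396a 5p	0.002
miR403	pmi-miR403_v1	TTAGATTCACGCACAAACTCG	21	16	ath-miR403 3p	0.002
miR408	pmi-miR408_v1	TGCACTGCCTCTTCCCTGGCT	21	88	smo-miR408 3p	0.002
miR408	pmi-miR408_v2	TGCACTGCCTCTTCCCTGGCTC	22	51	smo-miR408 3p	0.002
miR477	pmi-miR477_v1	AGAAGCCTTTGGGGGAGAGGG	21	5	ppt-miR477a 3p	0.022
miR477	pmi-miR477_v2	CTCTCCCTCAAAGGCTTCCA	20	3	ppt-miR477a 5p	0.004
miR529	pmi-miR529_v1	AGAAGAGAGAGAGCACAGCCC	21	289	ppt-miR529d 5p	0.002
miR529	pmi-miR529_v2	AGAAGAGGGAGAGCACAGCCC	21	256	ppt-miR529d 5p	0.008
miR529	pmi-miR529_v3	AGAAGAGAGAGAGCACAGCCT	21	23	bdi-miR529 5p	0.004
miR529	pmi-miR529_v4	GCTGTGCTCACTCTCTTCTGG	21	163	ppt-miR529d 3p	0.057
miR530/1030	pmi-miR530_v1	TCTGCATCTGCACCTGCACCC	21	17663	ppt-miR1030a 5p	0.004
miR530/1030	pmi-miR530_v2	TCTGCATCTGCACCTGCACCT	21	816	ppe-miR530 5p	0.004
miR535	pmi-miR535_v1	TGACGACGAGAGAGAGCACGC	21	19872	ppe-miR535b 5p	0.002
miR536	pmi-miR536_v1	TCGTGCCAAGCTGTGTGCAACC	22	26	ppt-miR536a 3p	0.002
miR1024	pmi-miR1024_v1	TCTGGTTGGATTGTAGGCCT	20	21	ppt-miR1024a 3p	0.004
miR1083	pmi-miR1083_v1	TAGCCTGGAACGAAGCACGGA	21	1755	smo-miR1083 5p	0.004
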