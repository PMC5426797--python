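# Putative conserved Lygodium japonicum targets of Pleopeltis minima miRNAs,
# transcribed from the published target table. Expectation values were produced by the
# psRNATarget complementarity score and are echoed as-printed (the external Lygodium
# transcriptome is not shipped, so they cannot be recomputed here).
family	locus	expectation	function	conservation
pmi-miR156	Locus_14997	1	SBP transcription factor	liverworts, moss, gymnosperms, angiosperms
pmi-miR159	Locus_7173	1.5	MYB transcription factor	gymnosperms, angiosperms
pmi-miR159	Locus_3676	2	RWP-RK domain transcription factor	same target as miR319 in liverworts
pmi-miR160	Locus_6056	0	Auxin response factor (ARF)-B3 DNA binding domain	liverworts, moss, Ceratopteris, gymnosperms, angiosperms
pmi-miR160	Locus_3364	1	Auxin response factor (ARF)-B3 DNA binding domain	liverworts, moss, Ceratopteris, gymnosperms, angiosperms
pmi-miR166	Locus_1230	3.0	Class III homeodomain-leucine zipper protein C3HDZ2	liverworts, moss, gymnosperms, angiosperms
pmi-miR168	Locus_158	4.0	Argonaute 1 (AGO1)	gymnosperms, angiosperms
pmi-miR171	Locus_11016	1.5	GRAS domain transcription factor (SCL6)	liverwort (Marchantia), moss, Ceratopteris, gymnosperms, angiosperms
pmi-miR172	Locus_9880	0.5	Apetala2 (AP2)	Ceratopteris, gymnosperms, angiosperms
pmi-miR172	Locus_1423	1	Apetala2 (AP2)	Ceratopteris, gymnosperms, angiosperms
pmi-miR319	Locus_7173	2.0	MYB transcription factor	liverwort (Marchantia), moss, gymnosperms, angiosperms
pmi-miR319	Locus_831	3.0	MYB transcription factor	liverwort (Marchantia), moss, gymnosperms, angiosperms
pmi-miR319	Locus_1866	3.0	MYB transcription factor	liverwort (Marchantia), moss, gymnosperms, angiosperms
pmi-miR319	Locus_3676	2.0	RWP-RK domain transcription factor	liverworts (Marchantia, Pellia)
pmi-miR390	Locus_39179	0.5	TAS3 tasi-RNA targeting ARF3/4	liverwort (Marchantia), moss, gymnosperms, angiosperms
pmi-miR390	Locus_20755	0.5	TAS3 tasi-RNA targeting ARF3/4	liverwort (Marchantia), moss, gymnosperms, angiosperms
pmi-miR408	Locus_5439	3.0	Polyphenol oxydase (PPO)	liverwort (Pellia)
pmi-miR529	Locus_14997	1	SBP domain transcription factor	liverwort (Marchantia), gymnosperms, angiosperms
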