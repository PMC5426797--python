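# Integrity constants checked by the fixture loader.
key	value
table1_rows	57
table1_families	23
table2_rows	18
table2_families	11
matrix_families	23
matrix_taxa	8
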