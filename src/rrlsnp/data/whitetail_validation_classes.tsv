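coverage	minor_allele_count	total_putative	n_tested	n_passing_qc	n_validated
3	1	6791	15	14	14
4	1	1951	15	13	13
4	2	497	12	12	12
5	1	778	12	12	10
5	2	255	12	9	7
6	1	467	12	9	7
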