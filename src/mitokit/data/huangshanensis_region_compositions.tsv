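# Published per-region nucleotide compositions of the T. huangshanensis
# mitogenome (GenBank PQ825598).  (J) = heavy/majority strand subset,
# (N) = light/minority strand subset.
region	size_bp	pct_A	pct_C	pct_G	pct_T
mitogenome	16497	34.3	23.9	11.6	30.2
PCGs	11405	32.8	25.8	10.5	31.0
PCGs(J)	10880	32.4	25.6	10.6	31.3
PCGs(N)	525	40.8	29.7	6.7	22.9
tRNAs	1509	36.4	20.1	13.9	29.6
tRNAs(J)	956	37.4	17.4	14.4	30.8
tRNAs(N)	553	34.7	24.8	13.0	27.5
rRNAs	2530	37.9	19.4	16.0	26.7
control_region	1064	38.3	20.8	9.7	31.3
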