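# Published whole-mitogenome nucleotide compositions of seven Typhlomys
# species/putative species (percentages as printed, 1 d.p.).  The printed
# A+T% / G+C% columns are carried verbatim: in the T. sp. 2 row the base
# cells sum to 100.7, so the printed totals are not recoverable from them.
taxon	length_bp	pct_A	pct_C	pct_G	pct_T	pct_GC	pct_AT
T. chapensis	17380	33.5	26.8	12.6	27.2	39.4	60.6
T. cinereus	16776	34.7	24.1	11.3	29.9	35.4	64.6
T. daloushanensis	16984	34.2	25.3	11.8	28.7	37.1	62.9
T. nanus	16665	33.9	25.9	12.3	28.0	38.2	61.8
T. huangshanensis	16497	34.3	23.9	11.6	30.2	35.5	64.5
T. fengjiensis	16487	34.5	24.5	11.7	29.3	36.2	63.8
T. sp. 2	16490	34.3	24.7	11.8	29.9	36.5	63.5
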