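# Per-locus novel-allele accounting over a 17-month operational window
# (1.43 M donors per locus). Columns: locus, samples typed, confirmed
# novel-allele observations, distinct novel sequences. Derived rates are
# always recomputed from these counts, never stored.
locus	samples	total_novel	distinct_novel
A	1430000	248	230
B	1430000	325	293
C	1430000	285	255
DRB1	1430000	1011	364
DQB1	1430000	941	464
DPB1	1430000	864	313
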