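# Reference cohort: ALK copy-number-gain category counts per concordance group.
category	positive_discordant	negative_discordant	positive_concordant
<=3	12	11	129
4-6	8	2	40
7-9	6	1	19
10+	7	3	1
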