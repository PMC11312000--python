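# Reference cohort: the 17 cases additionally analysed by panel sequencing.
# percent_rearranged is the FISH tri-colour read-out (primary tumour component
# for multi-component cases); pattern lists derived classes predominant-first;
# atypical=1 marks a sample dominated by guideline-uncountable (3'-deletion)
# configurations; ngs_fusion_partner is the called ALK fusion partner or none.
case_id	sex	age	percent_rearranged	pattern	atypical	ihc	ngs_fusion_partner
1	M	69	26	translocation+inversion	0	negative	none
2	M	60	68	inversion	0	negative	none
3	M	53	64	inversion	0	negative	EML4
4	M	70	44	five_prime_deletion+translocation	0	negative	none
5	M	68	30	translocation+interstitial_deletion	0	negative	none
6	F	70	26	inversion	0	negative	none
7	M	64	18	five_prime_deletion+inversion	0	negative	none
8	F	75	17	five_prime_deletion+translocation+inversion	0	negative	none
9	M	78	60	five_prime_deletion	0	negative	none
10	M	63	16	translocation+inversion	0	negative	none
11	F	79	4	none	0	negative	none
12	F	77	4	none	1	positive	EML4
13	F	71	2	none	0	positive	CSFT3
14	F	56	50	inversion	0	positive	EML4
15	F	73	48	interstitial_deletion+inversion	0	positive	EML4
16	M	48	62	five_prime_deletion+interstitial_deletion	0	positive	HIP1
17	F	64	90	interstitial_deletion	0	positive	EML4
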