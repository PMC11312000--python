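# Reference cohort: counts of derived rearrangement-pattern combinations in
# ALK FISH-positive samples retested with the tri-colour ALK/EML4 fusion probe,
# split by IHC concordance group and by whether at least one signal variant
# reached the 15% cut-off on its own (threshold) or the positive result was
# composed of variants each below 15% (subthreshold).
# combination lists pattern classes predominant-first, joined by '+'.
cohort	combination	subthreshold	threshold
discordant	inversion	5	5
discordant	interstitial_deletion	0	0
discordant	translocation	0	0
discordant	five_prime_deletion	0	2
discordant	interstitial_deletion+inversion	0	3
discordant	five_prime_deletion+inversion	2	0
discordant	five_prime_deletion+translocation	0	4
discordant	interstitial_deletion+translocation	1	0
discordant	translocation+inversion	1	0
discordant	inversion+translocation	3	0
discordant	five_prime_deletion+translocation+inversion	1	2
concordant	inversion	2	131
concordant	interstitial_deletion	0	4
concordant	translocation	0	0
concordant	five_prime_deletion	0	0
concordant	interstitial_deletion+inversion	0	21
concordant	five_prime_deletion+interstitial_deletion	0	4
concordant	translocation+interstitial_deletion	0	1
concordant	interstitial_deletion+translocation	0	1
concordant	translocation+inversion	0	3
concordant	five_prime_deletion+translocation+inversion	0	1
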