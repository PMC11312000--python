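# Reference cohort: IHC/FISH concordance class counts (2683 cases with both
# assays evaluable). "initial" counts precede the IHC reevaluation step in
# which dot-like staining on repeat moved 5 of 9 repeated positive-discordant
# cases to positive concordant.
key	value
n_analyzed	2683
pos_conc_initial	184
pos_disc_initial	38
neg_disc	17
neg_conc	2444
repeats_performed	9
repeats_dot_like	5
pos_conc_final	189
pos_disc_final	33
fish_positive	222
fish_negative	2461
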