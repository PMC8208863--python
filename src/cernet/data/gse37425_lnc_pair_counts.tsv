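lnc_id	n_first	n_second	total
NONHSAT123397	7	313	320
ENST00000564619	6	298	304
NONHSAT077997	6	352	358
NONHSAT145473	5	252	257
NONHSAT104609	5	252	257
NR_027512.1	5	252	257
FR233072	5	263	268
NONHSAT083947	5	257	262
NONHSAT026319	5	251	256
NONHSAT033305	4	179	183
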