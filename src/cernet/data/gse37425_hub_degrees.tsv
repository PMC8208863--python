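node_id	degree	node_type	fold_change
Hsa-miR-3135b	248	mi	1.180132215
Hsa-miR-4758-5p	163	mi	1.121940431
Hsa-miR-4749-5p	131	mi	1.045117605
Hsa-miR-4649-5p	121	mi	1.124608718
Hsa-miR-3188	110	mi	1.475727733
Hsa-miR-1231	105	mi	1.205829903
Hsa-miR-455-3p	66	mi	1.000930169
Hsa-miR-486-5p	66	mi	1.051809938
Hsa-miR-4286	37	mi	-1.037989108
Hsa-miR-3609	32	mi	1.043174805
PAFAH1B2	8	m	-1.1099555
CFLAR	8	m	-1.076701125
NONHSAT123397	7	lnc	-2.415788663
MSR1	7	m	-2.200573263
ABL2	7	m	-1.399022013
TPM3	7	m	-1.386117525
FKBP5	7	m	-1.33889315
PEX5L	6	m	-1.940342225
AAK1	6	m	-1.661734963
RAB3IP	6	m	-1.554929325
ENST00000564619	6	lnc	-1.464096138
NONHSAT077997	6	lnc	-1.316733238
AKAP5	6	m	-1.24698225
NONHSAT145473	5	lnc	-1.4293997
NONHSAT104609	5	lnc	-1.2225913
NR_027512.1	5	lnc	-1.21770025
FR233072	5	lnc	-1.104499363
NONHSAT083947	5	lnc	-1.08422
NONHSAT026319	5	lnc	-1.052942563
NONHSAT033305	5	lnc	-2.450632488
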