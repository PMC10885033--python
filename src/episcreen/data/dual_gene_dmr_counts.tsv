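gene_id	n_hypo	n_hyper
ZNF556	1	0
CDH15	1	2
TRIM72	1	1
ANK1	2	1
MCF2L	2	3
DOK7	0	1
CNPY1	0	2
KCNJ12	0	3
ST8SIA5	0	1
ZIC1	0	14
VAX2	0	7
EN2	0	4
LBX1	0	4
PAX3	0	11
CHRD	1	0
FNDC5	0	0
PLCB4	0	0
MPP4	0	0
PTPRR	0	0
IL11	0	0
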