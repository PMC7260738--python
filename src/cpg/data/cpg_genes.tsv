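gene	role	chrom	base_pos
ALK	oncogene	2	29415640
APC	tsg	5	112043202
ATM	tsg	11	108093559
BAP1	tsg	3	52435020
BRCA1	tsg	17	41196312
BRCA2	tsg	13	32889611
BRIP1	tsg	17	59756547
CDK4	oncogene	12	58141510
CDKN2A	tsg	9	21967751
CHEK2	tsg	22	29083731
FH	tsg	1	241660903
KIT	oncogene	4	55524085
MET	oncogene	7	116312444
MLH1	tsg	3	37034841
MSH2	tsg	2	47630206
MSH6	tsg	2	48010221
NF1	tsg	17	29421945
PALB2	tsg	16	23614483
PMS2	tsg	7	6012870
POLE	tsg	12	133200348
PTEN	tsg	10	89623195
RAD51C	tsg	17	56769934
RAD51D	tsg	17	33426811
RB1	tsg	13	48877887
RECQL	tsg	12	21621904
RET	oncogene	10	43572517
SDHB	tsg	1	17345217
STK11	tsg	19	1205798
TP53	tsg	17	7571720
VHL	tsg	3	10183319
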