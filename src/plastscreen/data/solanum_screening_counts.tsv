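# Published per-marker screening counts for two Solanum clades
# (Potato clade: 3 plastome-derived sequences; Morelloid clade: 12 species).
# indel_chars = variable coded indel characters (combined count minus variable sites).
marker	clade	total_chars	variable	indel_chars	nuclear
ndhC-trnV	Morelloid	884	56	24	0
ycf1 part 1	Morelloid	1260	64	7	0
ycf1 part 2	Morelloid	1293	64	6	0
rpl32-trnL	Morelloid	1019	54	8	0
ycf1 part 3	Morelloid	1032	51	2	0
petL-psaJ	Morelloid	1217	48	4	0
trnK-rps16	Morelloid	746	36	6	0
ndhF-rpl32	Morelloid	772	36	4	0
trnT-L	Morelloid	1109	32	6	0
ndhF	Morelloid	967	34	0	0
trnS-G	Morelloid	692	26	8	0
atpB-rbcL	Morelloid	1266	22	5	0
clpP-psbB	Morelloid	1139	21	6	0
trnL-F	Morelloid	549	22	5	0
psbK-I	Morelloid	541	15	1	0
trnA-trnI	Morelloid	1265	3	1	0
ITS	Morelloid	614	72	11	1
waxy	Morelloid	715	67	15	1
ndhC-trnV	Potato	852	12	5	0
ycf1 part 1	Potato	1251	39	0	0
ycf1 part 2	Potato	1393	24	3	0
rpl32-trnL	Potato	982	36	8	0
ycf1 part 3	Potato	1037	27	1	0
petL-psaJ	Potato	1185	23	5	0
trnK-rps16	Potato	735	15	3	0
ndhF-rpl32	Potato	773	22	2	0
trnT-L	Potato	1117	10	3	0
ndhF	Potato	980	23	1	0
trnS-G	Potato	699	9	4	0
atpB-rbcL	Potato	1245	23	1	0
clpP-psbB	Potato	1149	43	5	0
trnL-F	Potato	544	3	1	0
psbK-I	Potato	537	5	2	0
trnA-trnI	Potato	1267	32	3	0
petN-psbM	Potato	999	24	4	0
rpoC1-rpoB	Potato	980	24	2	0
ITS	Potato	622	63	13	1
waxy	Potato	704	47	14	1
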