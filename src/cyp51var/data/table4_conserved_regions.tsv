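snp_id	protein_change	sift_label	sift_score	polyphen_label	polyphen_score	region	note
rs368261783	Y137C	damaging	0	Possibly damaging	0.497	SRS1
rs750743669	S138N	damaging	0.04	Benign	0.262	SRS1
rs758553106	R139C	damaging	0.03	Probably damaging	0.946	SRS1
rs140356336	R139H	tolerated	0.65	Benign	0.029	SRS1
COSM5500428	V144A	tolerated	0.29	Probably damaging	0.994	SRS1
rs312262912	Y151D	damaging	0	Probably damaging	0.962	SRS1
rs371492794	D152G	damaging	0.01	Probably damaging	0.988	SRS1
COSM1202901 rs755026542	D152N	damaging	0.01	Probably damaging	0.985	SRS1
rs776271983	A172V	tolerated	0.22	Benign	0.101	POR interaction
/	L232P	damaging	0	Probably damaging	0.995	SRS2
COSM353554	Y233*	/	/	/	/	SRS2	Unknown
COSM2863985	W245S	damaging	0.01	Probably damaging	0.981	Azole interaction
rs753673809	W245Ter	/	/	/	/	Azole interaction	No protein
COSM1579448	W250S	damaging	0.02	Probably damaging	0.999	Azole interaction
rs200921006 COSM3663398	R258C	damaging	0	Probably damaging	0.999	SRS3
rs765961879 COSM1202902	R258H	damaging	0	Benign	0.93	SRS3
rs765961879	R258L	damaging	0.01	Benign	0.168	SRS3
rs745413412	H320P	damaging	0	Possibly damaging	0.899	SRS4
rs377725460	T325A	damaging	0.01	Benign	0.359	SRS4
rs760669078	P381T	tolerated	0.08	Probably damaging	0.990	SRS5
rs150090274	I383V	damaging	0.05	Benign	0.024	SRS5
rs150090274	I383L	tolerated	0.14	Benign	0.143	SRS5
COSM3698597	M384I	tolerated	0.34	Probably damaging	0.930	SRS5
rs759341868	I385F	damaging	0.01	Benign	0.075	SRS5
rs773893086	M386V	tolerated	0.12	Benign	0.376	SRS5
rs532896478	M386I	tolerated	1	Benign	0.044	SRS5
rs765119371	M387I	damaging	0.05	Possibly damaging	0.758	SRS5
COSM5986705	M387delM	/	/	/	/	SRS5	Unknown
rs748782320	R388Ter	/	/	/	/	SRS5	No protein
rs528934873	R452H	damaging	0.04	Benign	0.082	POR interaction
rs779786966	R452C	damaging	0	Benign	0.166	POR interaction
rs768113032	T492A	tolerated	0.15	Benign	0.117	SRS6
rs749633381	M493V	damaging	0.02	Possibly damaging	0.545	SRS6
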