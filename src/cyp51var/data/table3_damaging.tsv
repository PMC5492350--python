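snp_id	protein_change	sift_label	sift_score	polyphen_label	polyphen_score	region	note
rs372875744	N125H	Damaging	0.03	Probably damaging	0.993	Helix B
rs535433995	H177R	Damaging	0.01	Probably damaging	0.975	Helix D
rs151249652	E194C	Damaging	0.01	Probably damaging	0.984	Beta sheet 3-1
rs536125410	L253S	Damaging	0	Probably damaging	0.982	Loop between helix F''/G, surface
rs141009880	I274T	Damaging	0.01	Possibly damaging	0.892	Helix G
rs140702410	R277L	Damaging	0	Probably damaging	0.969	Helix G
rs140118347	A334S	Damaging	0.02	Possibly damaging	0.799	Helix I
rs554366054	L417R	Damaging	0.02	Probably damaging	1	Loop between helix K' and meander, surface
rs138109473	R431H	Damaging	0	Probably damaging	0.974	Meander
rs542915180	R454H	Damaging	0	Probably damaging	0.999	Cys pocket
rs563098505	Y462D	Damaging	0	Probably damaging	0.98	Helix L, next to cys pocket
rs553164028	R507K	damaging	0	Probably damaging	0.997	C-terminal of the protein
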