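structure_label	residue	occupancy_percent
WT	M384	24.5
WT	I385	65.9
WT	I383	1.5
R277L	M384	12.7
R277L	I385	30.1
R277L	I383	0.8
R431H	M493	6.3
R431H	I494	1.2
D152G	W245	10.8
D152G	M493	1.6
D152G	F240	0.8
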