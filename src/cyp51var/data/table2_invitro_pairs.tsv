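human_snp	invitro_mutants	mutant_effect	predicted_human_effect
Y137C	ratY131F/S; humanY137F; humanY137A	No protein, no activity; 55% expr, no activity, spectr. ok; Decrease in binding of substrate	No activity
R139H	ratR133G	Normal activity	Unknown
D152G/N	ratD146A; humanD152A	Normal express, 106% activity; 70% expression, 54% activity, 4 times decrease in turnover number	Decreased activity
Y233*	ratY227F	55% activity	Lower activity
H242R	humanH242A	Destabilization of the protein	Unknown effect
H320P	ratH314F/A/K/D; humanH320A	Lower activity (42.6, 34.9, 20.2, 14); Destabilization of protein, higher affinity for products	Lower activity of the enzyme
T325A	ratT319A	Normal activity	Normal activity
R383V/L	humanR383A	Decrease in binding of substrate	Unknown
R388Ter	ratR382A	No protein	No protein
T492A	ratT486A	Normal activity	Normal activity
T496I	ratT490A	Normal activity	Normal activity
E375*	ratE369A	No protein	No protein
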