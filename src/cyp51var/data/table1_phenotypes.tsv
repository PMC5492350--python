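cdna	protein_change	phenotype	snp_id	population_frequency
c.1263G>A	W421Ter	Infantile onset central and lamellar cataract, developmental delay, brain white-matter abnormality, cryptogenic neonatal liver cirrhosis, spastic diplegia, increased lanosterol	rs141654764	0.00001647
c.935T>C	I312T	Infantile onset central and lamellar cataract, developmental delay, brain white-matter abnormality, cryptogenic neonatal liver cirrhosis, spastic diplegia, increased lanosterol	/	/
c.829C>T	R277C	Congenital cataract, neurologically and systemically normal	rs944015648	/
c.695T>C	L232P	Congenital cataract, neonatal fulminant hepatic failure, and global developmental delay	/	/
c.56T>C	V19A	Significant association with HDL-C level	rs2229188	0.00000825
c.56T>C	V19A	Significant association with hypertension	rs2229188	0.00000825
c.56T>C	V19A	Negative association with lifespan	rs2229188	0.00000825
c.56T>C	V19A	Association with hypertension	rs2229188	0.00000825
c.595+66A>G	/	Association with spontaneous premature labor	rs57218044	0.0363
c.1359T>C	/	Association with spontaneous premature labor	rs7797834	0.3596
c.*251G>C	/	Association with spontaneous premature labor	rs7793861	0.3644
c.*377T>C	/	Association with spontaneous premature labor	rs6465348	0.3576
c.*1016C>T	/	Association with spontaneous premature labor	rs12673910	0.1697
c.*377T>C	/	Association with lower LDL-C and TC in second trimester	rs6465348	0.3576
c.251G>C	/	Associated with glycemic HbA1c; association with expression of genes in pancreas	rs7793861	0.3644
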