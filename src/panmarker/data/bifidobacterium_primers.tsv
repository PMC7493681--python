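# Species- and subspecies-specific qPCR primer pairs of the published
# 22-target Bifidobacterium assay this toolkit models.
# taxon	name	sequence (5'-3')	product size (bp)
B. animalis subsp. animalis	Animalis-F	CAG ACC TCG CCG ATG AGC TA	110
	Animalis-R	ATA TCC GGC TTG ATC ACC TG
B. animalis subsp. lactis	Lactis-F	ACC TCA CCA ATC CGC TGT TC	137
	Lactis-R	GAT CCG CAT GGT GGA ACT CT
B. breve	Breve-F	TCA TCA CGG CAA GGT CAA GA	111
	Breve-R	GGC CAG AAC AGC TGG AAC AA
B. longum subsp. infantis	Infantis-F	ATG ATG CGC TGC CAC TGT TA	132
	Infantis-R	CGG TGA GCG TCA ATG TAT CT
B. longum subsp. suis	Suis-F	CAA GCC GGA TAT CGT CTT CG	130
	Suis-R	GAG GAT CGT GCC ATG CTG TC
B. longum subsp. longum	Longum-F	GTG TGG ATT ACC TGC CTA CC	179
	Longum-R	GTC GCC AAC CTT GAC CAC TT
B. bifidum	Bifidum-F	CTG GCA GCC GTG ACA CTA CT	102
	Bifidum-R	TGA ACT GGC CGT TAC GGT CT
B. gallicum	Gallicum-F	TCA CCA TCA CCA CCT CAC	182
	Gallicum-R	GTT CCA TTG TTC CCA TCC C
B. thermacidophilum	Thermacidophilum-F	CGT TAG AAC AGC GCC AAC AG	116
	Thermacidophilum-R	GCC GGC ATA TTC ATC GAG TC
B. thermophilum	Thermophilum-F	CCG ATG CCG ATA CAG TTC AA	109
	Thermophilum-R	TGT CAT CCG ACG CTT CAA GA
B. coryneforme	Coryneforme-F	TAA ATT CGT CCC CGC TTT GC	144
	Coryneforme-R	TCC TCA TCC TCC TCC ATA ACC
B. asteroides	Asteroides-F	GCC GTG GTC ACC ACA CTA TC	108
	Asteroides-R	GCG CAC TAT GTC ATT GTC TG
B. adolescentis	Adolescentis-F	GCT GAT ATC TGC GCT GTA CC	135
	Adolescentis-R	AAA CCA CCC AGT AGT CCT CC
B. pseudolongum	Pseudolongum-F	CAA GGC CAT CAA CTG GTT CA	120
	Pseudolongum-R	ACG TCG TGC TGC TCG AAT GT
B. cuniculi	Cuniculi-F	TGA AGG AAA CAC CGC CAA TC	127
	Cuniculi-R	ACC TCC CTC TGA GCC TTG AC
B. gallinarum	Gallinarum-F	CGA CGA AAC ATT ACG CAT CC	163
	Gallinarum-R	ATG AAA TCC ACT TCG CCA CC
B. scardovii	Scardovii-F	CGC AGG CAC TCG CTG TAC TA	102
	Scardovii-R	GGC GTA ACG TCT CAG TAT CA
B. pseudocatenulatum	Pseudocatenulatum-F	ACC TAC GAT TTC TCC CTC TCC	173
	Pseudocatenulatum-R	CTC CAG CAA AGC CAA CGA AC
B. angulatum	Angulatum-F	TGC GGA TAC CAT CGA AGA AC	101
	Angulatum-R	TTC GCG ACA TCC ATT GAC TG
B. dentium	Dentium-F	GCG ACC GCT TCC ATC ATT AT	123
	Dentium-R	GGA GAT GCC GTC CTT AGA TT
B. tsurumiense	Tsurumiense-F	TGC GGT TCA ACC AAG CTT AC	167
	Tsurumiense-R	TCG TCG TCA CCA GAT TCT TC
B. catenulatum	Catenulatum-F	CGC CAA CGC AGT AGT GCA TA	106
	Catenulatum-R	TAG GCC ACC TGG ATT CGA TA
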