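# Taxon vocabulary of the 22-target assay: species and their subspecies.
# kind is one of species, subspecies (with parent), nonspecific.
label	kind	parent
B. animalis	species
B. animalis subsp. animalis	subspecies	B. animalis
B. animalis subsp. lactis	subspecies	B. animalis
B. longum	species
B. longum subsp. longum	subspecies	B. longum
B. longum subsp. infantis	subspecies	B. longum
B. longum subsp. suis	subspecies	B. longum
B. breve	species
B. bifidum	species
B. gallicum	species
B. thermacidophilum	species
B. thermophilum	species
B. coryneforme	species
B. asteroides	species
B. adolescentis	species
B. pseudolongum	species
B. cuniculi	species
B. gallinarum	species
B. scardovii	species
B. pseudocatenulatum	species
B. angulatum	species
B. dentium	species
B. tsurumiense	species
B. catenulatum	species
Lactic acid bacteria	nonspecific
Bifidus	nonspecific
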