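# Published standard-curve fits (Ct vs log10 CFU/mL) for the four
# Bifidobacterium targets most used in probiotic products.
taxon	slope	intercept	r_squared	reported_efficiency_percent
B. animalis subsp. lactis	-3.564	18.03	0.998	90.788
B. bifidum	-3.438	17.713	0.998	95.359
B. breve	-3.448	18.169	0.998	94.987
B. longum subsp. infantis	-3.312	17.727	0.998	100.424
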