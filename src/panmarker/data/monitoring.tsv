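# Label claims versus assay detections for 26 probiotic (A*) and 7 dairy
# (B*) products surveyed with the 22-target Bifidobacterium assay.
# Taxa within a cell are separated by " | ".
product_id	labeled	detected
A1	B. longum	B. longum subsp. longum
A2	B. bifidum | B. longum	B. bifidum | B. longum subsp. longum
A3	B. animalis subsp. lactis	B. animalis subsp. lactis
A4	B. animalis subsp. lactis	B. animalis subsp. lactis
A5	B. animalis subsp. lactis	B. animalis subsp. lactis
A6	B. animalis subsp. lactis	B. animalis subsp. lactis
A7	B. bifidum | B. breve | B. longum	B. bifidum | B. breve | B. longum subsp. longum
A8	B. animalis subsp. lactis | B. bifidum	B. animalis subsp. lactis | B. bifidum
A9	B. animalis subsp. lactis | B. bifidum	B. animalis subsp. lactis | B. bifidum
A10	B. breve | B. longum subsp. longum	B. breve | B. longum subsp. longum
A11	B. animalis subsp. lactis | B. bifidum | B. breve	B. animalis subsp. lactis | B. bifidum | B. breve
A12	B. breve | B. longum | B. longum subsp. infantis	B. breve | B. longum subsp. longum | B. longum subsp. infantis
A13	B. animalis subsp. lactis | B. breve | B. longum	B. animalis subsp. lactis | B. breve | B. longum subsp. longum
A14	B. animalis subsp. lactis | B. bifidum | B. breve	B. animalis subsp. lactis | B. bifidum | B. breve
A15	B. animalis subsp. lactis | B. bifidum | B. breve	B. animalis subsp. lactis | B. bifidum | B. breve
A16	B. animalis subsp. lactis | B. bifidum | B. breve	B. animalis subsp. lactis | B. bifidum | B. breve
A17	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum
A18	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum
A19	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum
A20	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
A21	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum
A22	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
A23	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
A24	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
A25	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum | B. longum subsp. infantis	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
A26	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum | B. longum subsp. infantis	B. animalis subsp. lactis | B. bifidum | B. breve | B. longum subsp. longum | B. longum subsp. infantis
B1	B. animalis subsp. lactis	B. animalis subsp. lactis
B2	B. animalis subsp. lactis	B. animalis subsp. lactis
B3	B. animalis subsp. lactis	B. animalis subsp. lactis
B4	Bifidus | Lactic acid bacteria	B. animalis subsp. lactis
B5	Bifidus | Lactic acid bacteria	B. animalis subsp. lactis | B. longum subsp. longum
B6	Lactic acid bacteria	B. animalis subsp. lactis
B7	Lactic acid bacteria	B. animalis subsp. lactis
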