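protein	accession	empai_aff1	empai_eff1
Protein AFF-1 anchor cell fusion failure-1	gi|193204255	2.07
Protein EFF-1, isoform a	gi|71982882		1.66
Histone H2B homologue	gi|156371481	1.78	1.78
Histone cluster 1, H2ag-like	gi|291410763		1
Actin family	gi|178045	1.05	0.35
Hemoglobin fetal subunit beta	gi|62460494	0.78	1.62
Serum albumin	gi|1351907	0.2	0.31
Galectin-3-binding protein	gi|81861611	0.41	0.63
60S acidic ribosomal protein P2	gi|133062		0.79
40S ribosomal protein SA-like	gi|296190805		0.47
Guanine nucleotide-binding protein subunit beta-2-like 1	gi|5174447		0.56
Glyceraldehyde-3-phosphate dehydrogenase-like	gi|488563203		0.55
Laminin-binding protein	gi|34234		0.49
Tubulin beta-3 chain	gi|12963615		0.37
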