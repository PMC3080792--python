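# Reference dataset: proteins annotated to DNA packaging that were detected
# in the rat lung endothelial plasma-membrane fraction, with their reported
# subcellular specificity.
protein_id	accession	description	abundance_P_ng_per_mg	sin_P	sin_H	ratio_PH	locations
JS40011197	O88807	Protein-arginine deiminase type-4	0				Cytoplasm
JS40071128	O88764	Death-associated protein kinase 3	0				Nuclear; cytoplasm
JS40026124	Q923V8	15 kDa selenoprotein precursor	0				Endoplasmic reticulum lumen
JS40021817	Q63945	Protein SET	0				Cytoplasm, Endoplasmic reticulum, Nucleus
JS40021552	Q9Z2G8	Nucleosome assembly protein 1-like 1	0				Nucleus, Melanosome
JS40048134	NP_445899.1	Histone deacetylase 2	0				Nucleus
JS40016703	Q6AYU1	Mortality factor 4-like protein 1	0				Nucleus
JS40021952	Q6P747	Heterochromatin protein 1, binding protein 3	0				Nucleus
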