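# Reference dataset: proteins regarded as primarily neuron-associated or
# neuron-restricted that were detected in the rat lung endothelial
# plasma-membrane fraction. abundance in ng per mg membrane protein;
# ratio_PH of 'inf' means detected in the membrane fraction only.
protein_id	accession	description	abundance_P_ng_per_mg	sin_P	sin_H	ratio_PH	locations
JS40001915	Q9Z270	Vesicle-associated membrane protein-associated protein A	645.54			0.523	Plasma membrane; vesicle
JS40008100	NP_001100068	catenin (cadherin associated protein), alpha 2 (N-catenin)	461.25			3.92	plasma membrane, Cytoskeleton, cell junction
JS40003261	Q9JK11	Reticulon-4 (nogo)	343.33			1.09	Endoplasmic reticulum
JS40015951	Q9Z269	Vesicle-associated membrane protein-associated protein B	267.42			0.461	Plasma membrane; vesicle
JS40003589	Q9QWJ9	Neuropilin-1, CD304	218.03			2.342	Plasma membrane
JS40013915	Q9JLU4	Shank3 (Proline-rich synapse associated protein 2)	172.77			4.844	Plasma membrane; cytoplasm, synapse
JS40001396	Q64548	Reticulon-1	85.81			3.637	Endoplasmic reticulum
JS40046849	Q6GMN2	Brain-specific angiogenesis inhibitor 1-associated protein 2 (BAI1A2)	25.66			inf	Plasma membrane; cytoplasm, cell projection
JS40014656	O08816	Neural Wiskott-Aldrich syndrome protein (N-Wash)	16.95			inf	Cytoskeleton; nucleus
JS40028986	NP_001101576	Plexin-B2	14.73			0.553	Plasma membrane
JS40004987	Q63198	Contactin-1 (Neural cell surface protein F3)	7.97			inf	Plasma membrane
JS40001709	Q6RJR6	Reticulon 3 protein	2			416.78	golgi; ER
JS40039470	Q8NFP9	Neurobeachin	1.85			inf	Peripheral membrane, cytoplasm
JS40011947	P21263	Nestin	1.17			inf	unknown
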