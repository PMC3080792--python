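# Reference dataset: translation initiation and elongation factors quantified
# in the rat lung endothelial plasma-membrane fraction (P) versus total tissue
# homogenate (H). abundance in ng per mg membrane protein; ratio_PH of 'inf'
# means the protein was detected in P only.
protein_id	accession	description	abundance_P_ng_per_mg	sin_P	sin_H	ratio_PH	locations
JS40004190	NP_787032	eukaryotic translation elongation factor 1 alpha 1	18258.65			2.56	Cytoplasm
JS40005734	NP_001100433	eukaryotic translation initiation factor 1A, Y-linked	2626.9			10.755	undecided
JS40005646	NP_062229	eukaryotic translation initiation factor 2, subunit 1 alpha	2308.39			6.771	undecided
JS40001804	NP_001094012	eukaryotic translation initiation factor 2, subunit 3	775.64			16.697	undecided
JS40006902	NP_955412	Eukaryotic translation initiation factor 2, subunit 2 beta, 38 kDa	763.77			5.164	undecided
JS40001854	NP_001102719	eukaryotic elongation factor, selenocysteine-tRNA-specific	358.95			inf	Cytoplasm; Nuclear
JS40020543	EDM15826	eukaryotic translation initiation factor 3, subunit 6 interacting protein	317.75			1.972	Cytoplasm; ER
JS40021548	XP_226974	PREDICTED: similar to eukaryotic translation initiation factor 5A2	267.31			0.258	cytoplasm; ER
JS40011343	NP_001099762	eukaryotic translation initiation factor 3, subunit F	232.31			0.329	Cytoplasm
JS50132783	NP_001032429	eukaryotic translation initiation factor 6	228.67			inf	Cytoplasm; Nucleus
JS40017299	NP_001102269	Eukaryotic translation elongation factor 1 beta 2	147.59			0.922	undecided
JS40009434	P05197	Elongation factor 2	125.01			0.079	Cytoplasm
JS40023935	Q07205	Eukaryotic translation initiation factor 5	97.1			inf	undecided
JS40005388	NP_001103611	eukaryotic translation initiation factor 5B	96.07			4.506	Cytoplasm
JS40033059	NP_001040552	eukaryotic translation initiation factor 3 subunit A	92.23			0.59	Cytoplasm
JS40021779	NP_001099712	eukaryotic translation initiation factor 3, subunit K	74.25			inf	Cytoplasm; nucleus
JS40017420	NP_001004223	eukaryotic translation elongation factor 1 gamma	73.2			0.307	undecided
JS40038166	Q63186	Translation initiation factor eIF-2B subunit gamma	35.96			inf	undecided
JS40041107	Q64270	Translation initiation factor eIF-2B subunit alpha	34.34			inf	undecided
JS50104474	Q4G061	Eukaryotic translation initiation factor 3 subunit B	29.64			0.139	Cytoplasm
JS40046084	NP_001013122	Eukaryotic translation elongation factor 1 delta	24.97			0.293	undecided
JS40032823	Q8VHU4	Elongator complex protein 1	14.96			inf	cytoplasm; nucleus
JS40020615	NP_001099307	eukaryotic translation initiation factor 1	14.26			inf	undecided
JS50042945	Q3B8Q2	Eukaryotic initiation factor 4A-III	11.75			0.304	cytoplasm; nucleus
JS40069686	NP_001099765	Tu translation elongation factor, mitochondrial	8.17			0.07	Mitochondria
JS40039662	Q6P9U8	Eukaryotic translation initiation factor 3, subunit 3 gamma, 40 kDa	7.31			0.18	Cytoplasm
JS40041278	P70541	Translation initiation factor eIF-2B subunit delta	7.08			inf	undecided
JS40053968	NP_001102809	eukaryotic translation initiation factor 2A	4.9			inf	undecided
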