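drug_id	step1_deletion	step2_dissimilarity	step3_flux_similarity	step4_pathway
Ferulic Acid	1	1	1	0
Glycyrrhizic acid	0	0	1	1
Resveratrol	1	0	0	1
Scutellarein	0	0	0	1
Strychnine	0	0	0	1
Narciclasine	0	1	0	1
Hydroxysafflor yellow A	0	1	1	0
Salvianolic Acid B	0	1	1	0
Daidzin	0	0	1	0
Macrozamin	0	0	1	0
Chelerythrine	0	0	0	1
Chenodeoxycholic acid	0	0	0	1
Emodin	0	0	0	1
Tetrahydropalmatine	0	0	0	1
Bacopaside I	0	0	1	0
Ethyl caffeate	0	0	1	0
Ginsenoside Rb1	0	0	1	0
Hypaconitine	0	0	1	0
Salidroside	0	0	1	0
Salvianic acid A sodium	0	0	1	0
Schizandrin	0	0	1	0
Bruceine D	0	1	0	0
Osthole	0	0	0	1
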