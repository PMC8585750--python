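species	cnl	tnl	rnl	total_nbs	predicted_proteins	proportion_pct	genome_size_mb
Aquilegia caerulea	231	1	1	233	41063	0.57	306
Nymphaea colorata	234	115	11	360	31589	1.14	409
Akebia trifoliata	50	19	4	73	24138	0.30	645
Amborella trichopoda	84	25	1	110	31494	0.35	706
Arabidopsis thaliana	55	94	-	149	38311	0.39	125
Carica papaya	33	20	1	54	24742	0.22	372
Populus trichocarpa	236	123	-	359	41444	0.87	410
Vitis vinifera	241	111	-	352	29585	1.19	505
Solanum lycopersicum	222	31	2	255	34727	0.73	739
Oryza sativa L.	535	0	-	535	37544	1.42	389
Dioscorea rotundata	166	0	1	167	26198	0.64	594
Setaria italica	96	0	-	96	35844	0.27	406
Triticum aestivum L.	2148	5	3	2151	107891	1.99	15770
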