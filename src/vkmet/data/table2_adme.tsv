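compound_id	name	ob	dl
GE01	citric acid	56.22	0.05
GE02	OXL	29.68	0.01
GE03	24-Methylenecycloartanol	10.4	0.79
GE04	beta-sitosterol	5.84	0.71
GE05	20-O-(2,3-dimethylbutanoyl)-13-O-dodecanoylingenol	24.17	0.61
GE06	3-O-Benzoyl-20-deoxyingenol	12.27	0.8
GE07	3-O-benzoyl-13-O-dodecanoylingenol	28.74	0.57
GE08	5-O-Benzoyl-20-deoxyingenol	13.52	0.79
GE09	[(1S,2R,5S,6R)-6-methyl-2-methylol-norpinan-6-yl]methanol	24.87	0.07
GE10	Euphorbetin	35.89	0.54
GE11	(3S,5R,10S,13R,14R,17R)-17-[(1R)-1,5-dimethyl-4-methylenehexyl]-4,4,10,13,14-pentamethyl-2,3,5,6,7,11,12,15,16,17-decahydro-1H-cyclopenta[a]phenanthren-3-ol	42.37	0.77
GE12	Euponin	18.64	0.49
GE13	Karacolidine	60.53	0.71
GE14	20-O-Benzoyl-13-O-dodeeanoyl ingenol	28.65	0.56
GE15	(1S,4aS,10aR)-7-isopropyl-1,4a-dimethyl-5,8-dioxo-2,3,4,9,10,10a-hexahydrophenanthrene-1-carboxylic acid	29.08	0.35
GE16	kansuinin A	44.52	0.55
GE17	kansuiphorin A	21.67	0.22
GE18	kansuiphorin B	19.16	0.2
GE19	NSC 403164	8.51	0.75
GE20	Euphol	42.12	0.75
GE21	20-OD-ingenol Z	32.05	0.85
GE22	Kanziol	41.65	0.75
GE23	Glycerite	14.97	0.03
GE24	3-O-(2,3-Dimethylbutanoyl)-13-O-decanoyl ingenol	24.75	0.71
GE25	3-O-(2,3-Dimethylbutanoyl)-13-O-dodecanoyl-20-O-acetylingenol	25.44	0.54
GE26	3-O-(2,3-Dimethylbutanoyl)-13-O-dodecanoyl-20-deoxyingenol	30.82	0.65
GE27	3-O-(2,3-dimethyl-butanoyl)-13-dodecanoylingenol	24.3	0.63
GE28	Isoscopoletin	23.46	0.08
GE29	Scopoletol	27.77	0.08
GE30	palmitic acid	19.3	0.1
GE31	HMF	45.07	0.02
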