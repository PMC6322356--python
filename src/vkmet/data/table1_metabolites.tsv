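no	rt	mz	mass_error_ppm	vip	metabolite	adduct	formula	kegg_id	trend	pathways
S1	1.18	160.0698	8.7	2.6	Indoleacetaldehyde	M+H	C10H9NO	C00637	down	Tryptophan metabolism
S2	2.88	514.2942	5.0	1.6	Taurocholic acid	M-H	C26H45NO7S	C05122	up	Primary bile acid biosynthesis; Taurine and hypotaurine metabolism
S3	3.91	498.2991	4.8	2.1	Taurochenodesoxycholic acid	M-H	C26H45NO6S	C05465	up	Primary bile acid biosynthesis
S4	4.46	407.2886	2.4	5.2	Cholic acid	M-H	C24H40O5	C00695	up	Primary bile acid biosynthesis
S5	4.79	318.2912	-5.3	1.9	Phytosphingosine	M+H	C18H39NO3	C12144	up	Sphingolipid metabolism
S6	6.15	391.2934	2.0	2.1	Chenodeoxycholic acid	M-H	C24H40O4	C02528	down	Primary bile acid biosynthesis
S7	8.27	522.3438	-8.2	2.3	LysoPC(18:1)	M+H	C26H52NO7P	C04230	up	Glycerophospholipid metabolism
S8	10.88	327.2400	-0.6	2.8	Docosahexaenoic acid	M-H	C22H32O2	C06429	down	Biosynthesis of unsaturated fatty acids
U1	3.73	340.0978	7.1	2.8	5-Hydroxy-6-methoxyindole glucuronide	M+H	C15H17NO8	C03033	down	Pentose and glucuronate interconversions
U2	6.46	413.2165	-9.0	1.5	Prostaglandin G2	M+FA-H	C20H32O6	C05956	up	Arachidonic acid metabolism
U3	6.71	472.1692	7.0	1.8	10-Formyltetrahydrofolate	M-H	C20H23N7O7	C00234	up	One carbon pool by folate; Glyoxylate and dicarboxylate metabolism; Aminoacyl-tRNA biosynthesis
U4	7.22	255.0563	-3.5	4.0	5-L-Glutamyl-taurine	M+H	C7H14N2O6S	C05844	down	Taurine and hypotaurine metabolism
U5	8.96	377.1403	5.6	2.1	Riboflavin	M+H	C17H20N4O6	C00255	down	Riboflavin metabolism
U6	9.07	331.1939	2.1	1.9	Androstenedione	M+FA-H	C19H26O2	C00280	down	Steroid hormone biosynthesis
U7	9.64	331.1973	-4.2	1.7	11b-Hydroxyprogesterone	M-H	C20H28O4	C05498	down	Steroid hormone biosynthesis
U8	10.48	318.2924	-1.6	2.6	Phytosphingosine	M+H	C18H39NO3	C12144	up	Sphingolipid metabolism
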