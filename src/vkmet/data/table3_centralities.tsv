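node	description	aspl	betweenness	r_printed
HSP90AA1	Heat shock protein HSP 90-alpha	2.17	0.06665	0.0000
PCNA	proliferating cell nuclear antigen	2.37	0.00782	0.1193
ANXA2	annexin A2	2.40	0.01316	0.1352
PRDX6	peroxiredoxin 6	2.53	0.02880	0.1455
PC	pyruvate carboxylase	2.61	0.00365	0.1696
ALB	albumin	2.61	0.01804	0.1797
SOD2	superoxide dismutase 2	2.63	0.02969	0.2294
APOA1	apolipoprotein A-I	2.68	0.01036	0.3243
FGA	fibrinogen alpha chain	2.80	0.00247	0.4764
CTH	cystathionase	3.07	0.00195	0.6409
AKR1C2	aldo-keto reductase family 1, member C2	3.15	0.00131	0.8362
CES1	carboxylesterase 1	3.64	0.00184	0.8523
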