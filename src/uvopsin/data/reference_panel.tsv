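# Default SWS1 reference panel. lambda_max_nm values are package defaults chosen
# consistent with the published short (356-362 nm) / long (368-370 nm) damselfish
# SWS1 classes; users should replace them with values from the cited expression /
# MSP studies before quantitative use. Non-focal sites carry the package's SWS1
# consensus residues. synthetic: stands in for the original curated panel.
species	gene	lambda_max_nm	method	is_damselfish	s46	s49	s52	s86	s90	s91	s93	s97	s109	s113	s114	s116	s118	s265	s125
Pomacentrus_amboinensis	SWS1	360	MSP	1	F	L	F	F	S	V	T	A	A	E	A	S	A	W	S
Pomacentrus_coelestis	SWS1	362	MSP	1	F	L	F	F	S	V	T	A	A	E	A	S	A	W	S
Dascyllus_trimaculatus	SWS1	368	MSP	1	F	L	F	F	S	V	T	A	A	E	S	S	S	W	A
Oreochromis_niloticus	SWS1	360	in-vitro	0	F	L	F	F	S	V	T	A	A	E	A	S	A	W	S
Metriaclima_zebra	SWS1	368	in-vitro	0	F	L	F	F	S	V	T	A	A	E	S	S	S	W	S
Oryzias_latipes	SWS1	356	in-vitro	0	F	L	F	F	S	V	T	A	A	E	A	S	A	W	S
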