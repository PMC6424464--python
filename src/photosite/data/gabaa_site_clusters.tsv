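protein_id	start	end	cluster_id	cluster_name	note
beta3	294	294	1	beta3(+)/alpha1(-) intersubunit	L294, KK202
beta3	308	309	1	beta3(+)/alpha1(-) intersubunit	G308/R309, KK200
alpha1	408	408	2	alpha1 intrasubunit	N408, KK200
alpha1	415	415	2	alpha1 intrasubunit	Y415, KK123
beta3	278	280	3	beta3 intrasubunit	VKA278-280, KK202; an alternative printed numbering (226-228) conflicts and is not used
beta3	442	442	3	beta3 intrasubunit	Y442, KK123
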