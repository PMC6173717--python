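#event_id	branch	ancestral_state	derived_state	ancestral_system	derived_system	scope
e01	stem_Pelophylax	unknown	Chr03	XY	XY	interspecific
e02	stem_Rana	unknown	unknown	XY	XY	interspecific
e03	R_dalmatina	Chr01	Chr05	XY	XY	interspecific
e04	R_kukunoris	Chr01	Chr05	XY	XY	interspecific
e05	R_blairi	Chr01	Chr05	XY	XY	interspecific
e06	R_pipiens	Chr01	Chr05	XY	XY	interspecific
e07	R_iberica	Chr01	Chr03	XY	XY	interspecific
e08	G_rugosa	Chr01	Chr08	XY	XY	interspecific
e09	R_japonica	Chr01	Chr03	XY	XY	intraspecific
e10	R_pipiens	Chr05	Chr02	XY	XY	intraspecific
e11	P_porosus	Chr03	Chr05	XY	XY	intraspecific
e12	G_rugosa	Chr08	Chr08	XY	ZW	homologous
e13	G_rugosa	Chr08	Chr08	XY	ZW	homologous
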