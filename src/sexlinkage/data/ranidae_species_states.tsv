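#species	chromosomes	system	source
R_arvalis	Chr01	XY	radseq
R_temporaria	Chr01,Chr02	XY	literature
R_italica	Chr01	XY	radseq
R_dalmatina	Chr05	XY	radseq
R_latastei	unknown	XY	radseq
R_iberica	Chr03	XY	radseq
R_macrocnemis	unknown	unknown	radseq
R_japonica	Chr01,Chr03	XY	both
R_ornativentris	unknown	unknown	radseq
R_chensinensis	unknown	unknown	radseq
R_uenoi	unknown	unknown	radseq
R_kukunoris	Chr05	XY	radseq
R_pipiens	Chr02,Chr05	XY	both
R_blairi	Chr05	XY	literature
R_berlandieri	unknown	XY	both
R_sphenocephala	unknown	XY	both
R_chiricahuensis	unknown	XY	radseq
R_tarahumarae	unknown	XY	radseq
R_yavapaiensis	unknown	XY	radseq
R_montezumae	Chr01	XY	radseq
R_catesbeiana	Chr01	XY	literature
R_clamitans	Chr01	XY	literature
R_sylvatica	Chr01	XY	literature
P_perezi	unknown	XY	radseq
P_lessonae	Chr03	XY	literature
P_saharicus	Chr03	XY	literature
P_porosus	Chr03,Chr05	XY	literature
G_rugosa	Chr08	XY,ZW	literature
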