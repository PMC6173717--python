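#chromosome	n_genes
Chr01	3200
Chr02	2900
Chr03	2600
Chr04	2400
Chr05	2100
Chr06	1900
Chr07	1800
Chr08	1500
Chr09	1300
Chr10	1200
Chr11	900
Chr12	800
Chr13	700
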