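species	age_group	complete
Eco	Prokaryota	true
Ngr	early Eukaryota	true
Tbr	early Eukaryota	false
Ath	Viridiplantae	true
Ddi	Unikonta	true
Sce	Opisthokonta	true
Tad	Metazoa	true
Nve	Radiata	true
Dme	Bilateria	true
Cin	Chordata	true
Dre	Vertebrata	true
Hsa	Mammalia	true
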