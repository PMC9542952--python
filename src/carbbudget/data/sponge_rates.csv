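species,rate_kg_m2_yr,provenance
Cliothosa delitrix,8.0,"synthetic default, literature magnitude"
Cliona caribbaea,6.0,"synthetic default, literature magnitude"
Cliona varians,2.5,"synthetic default, literature magnitude"
Pione lampa,3.0,"synthetic default, literature magnitude"
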