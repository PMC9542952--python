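taxon,g_rate,g_rate_se,provenance
Acropora cervicornis,15.0,2.0,"synthetic default, literature magnitude"
Acropora palmata,12.0,1.5,"synthetic default, literature magnitude"
Orbicella spp.,10.0,1.0,"synthetic default, literature magnitude"
Colpophyllia natans,6.0,0.8,"synthetic default, literature magnitude"
Montastraea cavernosa,5.0,0.6,"synthetic default, literature magnitude"
Siderastrea siderea,4.0,0.5,"synthetic default, literature magnitude"
Porites astreoides,3.5,0.5,"synthetic default, literature magnitude"
CCA,0.7,0.1,"synthetic default, literature magnitude"
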