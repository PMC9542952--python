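taxon,target_cover_pct,phase_year,provenance
Acropora palmata,5.0,2030,"synthetic default consistent with 15% Phase-1 total"
Acropora cervicornis,7.0,2030,"synthetic default consistent with 15% Phase-1 total"
Orbicella spp.,2.0,2030,"synthetic default consistent with 15% Phase-1 total"
Acropora palmata,8.0,2040,"synthetic default consistent with 25% Phase-2 total"
Acropora cervicornis,11.0,2040,"synthetic default consistent with 25% Phase-2 total"
Orbicella spp.,4.0,2040,"synthetic default consistent with 25% Phase-2 total"
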