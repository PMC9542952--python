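rate_kg_m2_yr,provenance
0.24,"synthetic default, literature magnitude"
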