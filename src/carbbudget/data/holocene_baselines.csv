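period,rate_mm_yr,provenance
mid_holocene,3.0,regional core-derived mean ~7000 BP
late_holocene,0.5,regional core-derived ceiling after ~3000 BP
last_millennium,0.17,regional core-derived mean over last 1000 yr
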