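test_size_cm,pmf,a,b,provenance
2,0.05,74.0,1.9,"synthetic default, literature magnitude"
3,0.10,74.0,1.9,"synthetic default, literature magnitude"
4,0.15,74.0,1.9,"synthetic default, literature magnitude"
5,0.20,74.0,1.9,"synthetic default, literature magnitude"
6,0.20,74.0,1.9,"synthetic default, literature magnitude"
7,0.15,74.0,1.9,"synthetic default, literature magnitude"
8,0.10,74.0,1.9,"synthetic default, literature magnitude"
9,0.05,74.0,1.9,"synthetic default, literature magnitude"
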