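phi,phi_se,rho,provenance
0.63,0.02,2.93,"regional framework porosity; grain density from conversion calibration"
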