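specimen,vg_eff_strain_rate_s,failure_stress_MPa
1-C1-F-L,5410,146.6
2-C1-F-L,6889,145.8
3-C2-F-L,4020,106.5
4-C2-F-L,5206,116.8
6-C3-F-L,2365,156.7
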