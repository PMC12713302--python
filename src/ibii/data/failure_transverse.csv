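specimen,vg_eff_strain_rate_s,failure_stress_MPa
12-C1-F-T,4985,58.3
13-C1-F-T,4985,67.3
14-C1-F-T,3486,78.0
15-C2-F-T,5455,62.8
16-C2-F-T,6173,54.8
18-C4-T-T,4022,45.4
19-C4-T-T,3086,53.6
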