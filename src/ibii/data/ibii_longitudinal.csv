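specimen,density_kg_m3,eff_strain_rate_s,ovf_Q11_GPa,ovf_nu12,ovf_nu21,sg_Q11_GPa,sg_Q66_GPa
1-C1-F-L,1980,-2086,21.3,0.23,0.11,23.54,
2-C1-F-L,2028,-1963,25.0,0.25,0.11,26.52,7.16
3-C2-F-L,2118,-1147,25.2,,,27.04,
4-C2-F-L,2118,-1999,27.7,0.31,0.17,27.76,7.62
5-C3-F-L,1934,-1149,20.0,,,20.13,
6-C3-F-L,2038,-1513,,,,29.07,
7-C3-F-L,2032,-1027,27.8,0.34,0.13,27.58,7.77
8-C3-F-L,2031,-1284,28.4,0.31,0.15,27.36,7.79
9-C3-F-L,1904,-1018,23.0,0.38,0.07,21.47,6.28
10-C4-T-L,2118,-846,,,,27.73,7.54
11-C4-T-L,1991,-1105,24.4,0.34,0.09,26.87,7.15
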