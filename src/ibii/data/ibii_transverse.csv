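specimen,density_kg_m3,eff_strain_rate_s,ovf_Q22_GPa,ovf_nu21,sg_Q22_GPa,sg_Q66_GPa
12-C1-F-T,1911,-1403,16.3,0.16,17.3,6.9
13-C1-F-T,1961,-1557,14.4,0.16,15.4,
14-C1-F-T,1964,-1255,15.6,0.16,15.8,6.8
15-C2-F-T,2043,-1268,17.8,0.20,16.6,6.6
16-C2-F-T,2040,-2569,15.3,0.21,18.3,4.6
17-C4-T-T,1853,-933,12.5,0.15,14.0,6.3
18-C4-T-T,1879,-1354,12.7,0.19,13.2,5.8
19-C4-T-T,1866,-1257,12.4,0.10,13.7,6.1
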