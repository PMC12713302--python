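specimen,E11_GPa,nu12
1-C1-QS-F-L,13.3,0.14
2-C1-QS-F-L,20.5,0.11
3-C1-QS-T-L,18.9,0.19
4-C1-QS-T-L,21.3,0.22
5-C1-QS-T-L,33.7,0.20
6-C2-QS-F-L,19.2,0.18
7-C2-QS-F-L,21.1,0.18
8-C2-QS-F-L,21.1,0.15
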