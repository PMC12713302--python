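specimen,E22_GPa,nu21
9-C1-QS-F-T,14.1,0.05
10-C1-QS-F-T,15.8,-0.53
11-C1-QS-F-T,14.8,0.11
12-C1-QS-F-T,14.6,0.15
13-C1-QS-T-T,15.4,0.10
14-C1-QS-T-T,8.6,0.11
15-C2-QS-F-T,7.6,0.14
16-C2-QS-F-T,13.9,0.25
17-C2-QS-F-T,15.2,0.11
18-C2-QS-F-T,13.0,0.46
19-C2-QS-F-T,11.6,-0.65
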