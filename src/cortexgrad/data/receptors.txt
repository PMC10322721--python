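AMPA
kainate
NMDA
GABAA
GABAA/BZ
GABAB
M1
M2
M3
5-HT1A
5-HT2A
alpha1
alpha2
D1
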