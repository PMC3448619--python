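animal,tumour_ratio
4,5.87
5,2.07
5,1.19
13,1.82
14,1.44
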