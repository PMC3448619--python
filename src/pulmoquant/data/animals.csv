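animal,genotype,sex,age_days,circumscribed_tumour,histology_mean,lung_ratio_mean
1,SPC-raf,M,447,N,3,1.03
2,SPC-raf,M,447,N,3.25,2.16
3,SPC-raf,M,261,N,2,1.32
4,SPC-myc,M,468,Y,1,0.92
5,SPC-myc,M,468,Y,1,0.9
6,wildtype,M,468,N,1,0.89
7,SPC-myc,F,559,N,1,1.38
8,SPC-myc,F,559,N,1,1.73
9,SPC-myc,M,568,N,1,1.27
10,SPC-raf,M,492,N,2,1.21
11,SPC-raf,F,492,N,1,1.63
12,SPC-raf,F,492,N,1,1.48
13,SPC-myc,M,323,Y,1,1.2
14,SPC-myc,M,323,Y,1,1.17
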