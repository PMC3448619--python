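position,description,mean_mGy,sd_mGy
1,Head (dorsal),2.1,0.3
2,Left hemithorax (dorsal),2.9,0.5
3,Right hemithorax (dorsal),2.7,0.6
4,Left thoracoabdominal junction (dorsal),3.5,0.7
5,Right thoracoabdominal junction (dorsal),3.5,0.8
6,Left abdomen (dorsal),4.3,1.6
7,Right abdomen (dorsal),4.3,0.7
8,Thorax (ventral),3.9,0.7
9,Abdomen/bladder region (ventral),12.4,8.2
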