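strain,n_mice,seg_mb,n_segments,n_genes
C57BL/6,27,,,
5A,24,70.7,2,820
6A,20,65,3,594
6C,26,92.28,5,713
49A,14,65.75,3,546
66H,17,51.31,3,312
103E,9,37.82,4,324
119H,22,42.3,2,456
120C,20,108.5,5,850
122C,22,46.12,2,429
122D,14,73.19,4,937
122F,9,21.79,2,257
135B,20,49.58,2,333
135E,23,17.41,1,186
137E,24,17.1,1,192
137F,17,46.01,2,366
137G,21,27.38,2,264
157F,24,40.61,2,455
157D,9,9.97,1,124
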