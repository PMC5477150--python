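peak,compound,st_r_min,rr,strt_reference,rr_reference
1,peak 1,9.271,0.226,False,False
2,peak 2,10.122,0.247,True,False
3,peak 3,25.143,0.615,False,False
4,peak 4,26.854,0.657,False,False
5,peak 5,32.437,0.794,False,False
6,peak 6,32.951,0.808,False,False
7,peak 7,35.843,0.878,False,False
8,peak 8,40.793,1.000,True,True
9,peak 9,43.254,1.061,False,False
10,peak 10,44.950,1.103,False,False
11,peak 11,46.937,1.152,False,False
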