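peak,compound,st_r_min,rr,strt_reference,rr_reference
1,Chonglou saponin VII,19.803,0.652,True,False
2,Chonglou saponin VI,22.156,0.729,False,False
3,Chonglou saponin II,30.319,1.000,False,True
4,Chonglou saponin I,33.035,1.090,True,False
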