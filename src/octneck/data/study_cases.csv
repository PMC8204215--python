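animal_id,location,device,n_implants,herniation,largest_gap_mm2,dsa_implant,dsa_180d
1,bifurcation,coils,11,Y,,2,2
2,sidewall,coils,6,N,,2,1
2,bifurcation,NGID,2,N,1.57,3,3
3,sidewall,coils,4,Y,,2,1
3,bifurcation,NGID,2,N,0.18,3,1
4,sidewall,NGID,1,N,0.55,2,1
4,bifurcation,NGID,2,N,1.30,3,3
5,sidewall,NGID,3,N,0.09,3,1
5,bifurcation,coils,6,Y,,3,1
6,sidewall,NGID,2,N,0.08,3,1
6,bifurcation,NGID,1,N,0.12,3,1
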