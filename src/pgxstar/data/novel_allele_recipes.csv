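haplotype,background,rsid,position,ref,alt,consequence,protein_change,count
1,*1,rs140900383,7471,C,T,missense,A226V,1
2,*1,rs141756339,9164,G,A,missense,R474Q,1
3,*1,rs565013903,7600,G,A,missense,R269P,3
4,*1,rs567606867,7004,G,A,missense,E215K,1
5,*2,rs368858603,7610,T,TT,frameshift,T272TX,2
6,*2,rs368858603,7610,T,TT,frameshift,T272TX,2
6,*2,rs374616348,6628,G,T,missense,V119L,2
7,*2,rs28371704,6002,A,G,missense,H94R,1
7,*2,rs28371703,5992,C,A,missense,L91M,1
8,*2,rs375715419,9115,A,G,missense,T458A,1
9,*2,rs376636053,6655,T,C,missense,W128R,1
10,*2,rs769157652,8873,G,A,missense,E410K,1
11,*17,rs747089665,8885,C,T,missense,R414C,1
11,*17,rs769157652,8873,G,A,missense,E410K,1
12,*17,rs1450231864,8231,T,C,missense,M347T,1
13,*29,rs76802407,6012,C,G,missense,D97E,5
14,*29,rs201006451,6767,C,T,missense,A165V,1
15,*29,rs536109057,5173,C,T,stop_gain,,2
16,*29,rs760940331,9096,G,A,missense,M451I,2
17,*41,rs141824015,8206,A,C,missense,I339L,4
18,*45,rs3915951,8177,G,T,missense,R329L,2
19,*70,rs16947,7870,C,T,missense,R296C,5
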