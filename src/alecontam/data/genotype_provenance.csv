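culture,timepoint,generation,IS1,frmR_1,frmR_2,gltA,plsX_1,plsX_2,fabF_1,fabF_2,marC_1,marC_2,marC_3,yffS,yfgO,iscR,srmB,P_yghB,trkH,rraA_1,rraA_2,plsB,rob_1,rob_2,rob_3,creC
A,T1,32,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
A,T2,62,s,s,s,s,s,s,s,s,s,i,s,s,i,s,s,s,s,s,s,s,s,s,s,s
A,T3,108,s,s,s,s,s,s,i,s,s,s,i,s,s,s,s,s,s,s,s,s,s,s,s,s
A,T4,126,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
A,T5,149,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
A,T6,177,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s
A,T7,226,s,i,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s
B,T1,32,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
B,T2,62,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s,s,s,i,s,s,s,s
B,T3,108,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
B,T4,126,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s,s,s,s
B,T5,149,i,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s,i,s,s,s,s,s,s,s
B,T6,177,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s
B,T7,226,s,s,i,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s
C,T1,32,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s
C,T2,62,s,s,s,s,s,s,s,s,s,i,s,s,s,s,i,s,s,s,s,s,s,s,s,s
C,T3,108,s,s,s,s,i,s,s,s,s,s,s,i,s,s,s,s,s,s,s,s,s,s,s,s
C,T4,126,s,s,s,s,i,s,s,i,s,s,s,s,s,s,s,i,s,s,s,s,s,s,s,s
C,T5,149,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s,s,i,s,s,s,s,s,s,i
C,T6,177,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s
C,T7,226,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,s,i,s
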