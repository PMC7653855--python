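culture,timepoint,generation,genotype
A,T1,32,
A,T2,62,marC_2;yfgO
A,T3,108,fabF_1;marC_3
A,T4,126,gltA;plsX_2;marC_1;rraA_1
A,T5,149,gltA;plsX_2;marC_1;rraA_1
A,T6,177,fabF_1;marC_3;P_yghB;rob_3
A,T7,226,frmR_1;fabF_1;marC_3;P_yghB;rob_3
B,T1,32,
B,T2,62,srmB;plsB
B,T3,108,fabF_1;marC_3
B,T4,126,fabF_1;marC_3;rraA_2
B,T5,149,IS1;fabF_1;marC_3;iscR;trkH
B,T6,177,fabF_1;marC_3;P_yghB;rob_2
B,T7,226,frmR_2;fabF_1;marC_3;P_yghB;rob_2
C,T1,32,
C,T2,62,marC_2;srmB
C,T3,108,plsX_1;yffS
C,T4,126,plsX_1;fabF_2;P_yghB
C,T5,149,iscR;trkH;rob_1;creC
C,T6,177,fabF_1;marC_3;P_yghB;rob_3
C,T7,226,fabF_1;marC_3;P_yghB;rob_3
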