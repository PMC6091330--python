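patient_id,sex,age,myeloma_type,impetus,stage_dss,stage_dsplus,stage_riss,treatment
1,M,57,IgG λ,"BM(4)A, F4.S.SP.ExtraSP(5), L4, PM, EM.EN(4)",IIIB,IIIB,III,None
2,M,38,IgG κ,"BM(3), F4.SP.ExtraSP(3), L4, EM.N.EN(4)",IIIA,IIIB,III,Chemotherapy
3,M,63,Nonsecretory,"BM(2), F4.SP.ExtraSP(4), L4, PM, EM.EN(3)",IIIB,IIB,III,None
4,M,68,Light chain κ,"BM(2), F4.SP.ExtraSP(4), L4, PM, EM.EN(3)",IIIB,IIIB,III,Chemotherapy
5,F,48,IgG κ,"BM(2), F4.SP.ExtraSP(4), L4, PM",IIIA,IIA,I,Chemotherapy + IMIDs
6,M,55,IgG κ,"BM(2), F4.SP.ExtraSP(4), L1, PM",IIIA,IIA,I,Chemotherapy + IMIDs
7,M,58,Light chain λ,"BM(2), F3.SP.ExtraSP(4), L3, PM",IIIA,IA,II,Chemotherapy
8,M,63,IgG λ,"BM(2), F4.S.SP.ExtraSP(4), L4",IIIA,IIIA,I,Chemotherapy
9,M,58,IgG κ,"BM(3), F4.SP.ExtraSP(4), L4, PM, EM.N.EN(5)",IIIB,IIIB,III,Chemotherapy
10,F,42,IgG κ,"BM(4), F1, L1",IIIA,IA,II,Chemotherapy + ASCT
11,M,60,Light chain κ,"BM(3), F4.SP.ExtraSP(4), L4, EM.EN(3)",IIIA,IIA,II,Chemotherapy + ASCT
12,M,63,IgG κ,"BM(2), F2.ExtraSP(4), L1",IIIA,IA,II,Chemotherapy
13,M,52,IgG λ,"BM(3)A, F4.S.SP.ExtraSP(3), L2, EM.EN(3)",IIIA,IIIA,III,None
14,M,67,IgG λ,"BM(4), F3.ExtraSP(4), L2",IIIA,IIA,II,Chemotherapy + allo-BMT
15,F,71,Light chain κ,"BM(5), F4.SP.ExtraSP(5), L3, PM, EM.N(5)",IIIA,IIIB,II,Chemotherapy + radiotherapy
16,F,64,IgG κ,"BM(3), F4.S.SP.ExtraSP(3), L3",IIIB,IIIB,III,Chemotherapy + IMIDs
17,F,67,IgG κ,"BM(4)A, F4.SP.ExtraSP(4), L4",IIIB,IIIB,III,None
18,M,34,IgG κ,"BM(3), F4.SP.ExtraSP(5), L3, PM, EM.EN(4)",IIIA,IIB,II,None
19,M,77,IgA κ,"BM(2)A, F3.SP(4), L1, PM, EM.N.EN(3)",IIIA,IIA,II,None
20,M,72,IgG κ,"BM(3), F3.SP.ExtraSP(4), L2, PM, EM.N(2)",IA,IIA,II,Chemotherapy
21,M,60,IgG λ,"BM(3), F4.SP.ExtraSP(5), L3, PM, EM.N(5)",IIIA,IIB,II,Chemotherapy + IMIDs
22,M,73,Light chain κ,"BM(3), F4.SP.ExtraSP(5), L2, EM.EN(5)",IIIB,IIIB,III,Chemotherapy + IMIDs
23,M,60,IgD λ,"BM(2), F2.SP(4), L2",IIIA,IA,III,Chemotherapy + IMIDs
24,M,59,Light chain κ,"BM(3), F3.SP.ExtraSP(5), L1, PM, EM.N(5)",IIA,IB,I,None
25,M,64,IgG κ,"BM(2), F2.SP(4), L4, PM",IIB,IIB,II,Chemotherapy + IMIDs
26,F,57,IgG λ,"BM(4)A, F4.SP.ExtraSP(4), L4, PM, EM.N(5)EN(4)",IIIA,IIIB,II,Chemotherapy
27,F,76,Light chain κ,"BM(4)A, F4.SP.ExtraSP(5), L4, PM, EM.EN(5)",IIIA,IIIB,III,None
28,F,58,IgA λ,"BM(4)A, F4.S.SP.ExtraSP(5), L4, EM.EN(5)",IIIA,IIIB,III,Chemotherapy + IMIDs
29,F,47,Light chain κ,"BM(2), F2.SP(5), L2, PM, EM.EN(5)",IIIA,IB,II,Chemotherapy + radiotherapy
30,M,69,IgG λ,"BM(2), F2.SP(2), L2, EM.EN(4)",IIIB,IB,II,Chemotherapy
31,M,65,IgG λ,"BM(2), PM, EM.EN(4)",IIIA,IB,III,Chemotherapy + ASCT
32,F,53,IgD λ,"BM(4)A, EM.EN(4)",IIIB,IB,II,Chemotherapy + IMIDs
33,M,50,IgG λ,"BM(5)A, F4.S.SP.ExtraSP(5), L4, EM.EN(4)",IIIB,IIIB,III,Chemotherapy
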