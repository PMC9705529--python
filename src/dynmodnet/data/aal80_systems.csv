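node_id,label,system
0,Precentral_L,SMN
1,Precentral_R,SMN
2,Rolandic_Oper_L,SMN
3,Rolandic_Oper_R,SMN
4,Supp_Motor_Area_L,SMN
5,Supp_Motor_Area_R,SMN
6,Postcentral_L,SMN
7,Postcentral_R,SMN
8,Paracentral_Lobule_L,SMN
9,Paracentral_Lobule_R,SMN
10,Frontal_Sup_Medial_L,DMN
11,Frontal_Sup_Medial_R,DMN
12,Frontal_Med_Orb_L,DMN
13,Frontal_Med_Orb_R,DMN
14,Cingulum_Ant_L,DMN
15,Cingulum_Ant_R,DMN
16,Cingulum_Post_L,DMN
17,Cingulum_Post_R,DMN
18,Hippocampus_L,DMN
19,Hippocampus_R,DMN
20,ParaHippocampal_L,DMN
21,ParaHippocampal_R,DMN
22,Angular_L,DMN
23,Angular_R,DMN
24,Precuneus_L,DMN
25,Precuneus_R,DMN
26,Temporal_Mid_L,DMN
27,Temporal_Mid_R,DMN
28,Calcarine_L,VN
29,Calcarine_R,VN
30,Cuneus_L,VN
31,Cuneus_R,VN
32,Lingual_L,VN
33,Lingual_R,VN
34,Occipital_Sup_L,VN
35,Occipital_Sup_R,VN
36,Occipital_Mid_L,VN
37,Occipital_Mid_R,VN
38,Occipital_Inf_L,VN
39,Occipital_Inf_R,VN
40,Fusiform_L,VN
41,Fusiform_R,VN
42,Frontal_Mid_L,ATN
43,Frontal_Mid_R,ATN
44,Parietal_Sup_L,ATN
45,Parietal_Sup_R,ATN
46,Parietal_Inf_L,ATN
47,Parietal_Inf_R,ATN
48,SupraMarginal_L,ATN
49,SupraMarginal_R,ATN
50,Frontal_Inf_Oper_L,TPN
51,Frontal_Inf_Oper_R,TPN
52,Frontal_Inf_Tri_L,TPN
53,Frontal_Inf_Tri_R,TPN
54,Insula_L,TPN
55,Insula_R,TPN
56,Cingulum_Mid_L,TPN
57,Cingulum_Mid_R,TPN
58,Frontal_Sup_L,Others
59,Frontal_Sup_R,Others
60,Frontal_Sup_Orb_L,Others
61,Frontal_Sup_Orb_R,Others
62,Frontal_Mid_Orb_L,Others
63,Frontal_Mid_Orb_R,Others
64,Frontal_Inf_Orb_L,Others
65,Frontal_Inf_Orb_R,Others
66,Olfactory_L,Others
67,Olfactory_R,Others
68,Rectus_L,Others
69,Rectus_R,Others
70,Heschl_L,Others
71,Heschl_R,Others
72,Temporal_Sup_L,Others
73,Temporal_Sup_R,Others
74,Temporal_Pole_Sup_L,Others
75,Temporal_Pole_Sup_R,Others
76,Temporal_Pole_Mid_L,Others
77,Temporal_Pole_Mid_R,Others
78,Temporal_Inf_L,Others
79,Temporal_Inf_R,Others
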