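id,name,parent_id,length_cm,radius_cm,thickness_cm,E_dyn_cm2,terminal_R
1,ascending_aorta_a,,2.0,1.885,0.2119,4000000.0,
2,r_coronary,1.0,10.0,0.195,0.0637,8000000.0,71651.05200000001
3,ascending_aorta_b,1.0,2.0,1.872,0.2106,4000000.0,
4,l_coronary,3.0,10.0,0.221,0.0676,8000000.0,47767.36800000001
5,ascending_aorta_c,3.0,2.0,1.846,0.208,4000000.0,
6,brachiocephalic,5.0,3.4,0.806,0.1118,4000000.0,
7,aortic_arch_a,5.0,2.0,1.625,0.1794,4000000.0,
8,r_subclavian,6.0,3.4,0.546,0.0871,4000000.0,
9,r_common_carotid,6.0,17.0,0.481,0.0819,4000000.0,
10,r_vertebral,8.0,14.8,0.247,0.0585,8000000.0,95534.73600000002
11,r_subclavian_b,8.0,6.8,0.52,0.0858,4000000.0,
12,r_brachial,11.0,42.2,0.416,0.0871,4000000.0,
13,r_radial,12.0,23.5,0.208,0.0559,8000000.0,95534.73600000002
14,r_ulnar,12.0,23.9,0.26,0.0598,8000000.0,71651.05200000001
15,r_external_carotid,9.0,11.3,0.195,0.0546,8000000.0,71651.05200000001
16,r_internal_carotid,9.0,17.2,0.26,0.0585,8000000.0,35825.526000000005
17,l_common_carotid,7.0,20.8,0.481,0.0819,4000000.0,
18,aortic_arch_b,7.0,3.9,1.482,0.1651,4000000.0,
19,l_external_carotid,17.0,11.3,0.195,0.0546,8000000.0,71651.05200000001
20,l_internal_carotid,17.0,17.2,0.26,0.0585,8000000.0,35825.526000000005
21,l_subclavian,18.0,3.4,0.546,0.0871,4000000.0,
22,thoracic_aorta_a,18.0,5.2,1.3,0.143,4000000.0,
23,l_vertebral,21.0,14.8,0.247,0.0585,8000000.0,95534.73600000002
24,l_subclavian_b,21.0,6.8,0.52,0.0858,4000000.0,
25,l_brachial,24.0,42.2,0.416,0.0871,4000000.0,
26,l_radial,25.0,23.5,0.208,0.0559,8000000.0,95534.73600000002
27,l_ulnar,25.0,23.9,0.26,0.0598,8000000.0,71651.05200000001
28,intercostals,22.0,8.0,0.26,0.0637,4000000.0,35825.526000000005
29,thoracic_aorta_b,22.0,10.4,0.8775,0.1066,4000000.0,
30,celiac,29.0,1.0,0.507,0.0832,4000000.0,
31,abdominal_aorta_a,29.0,5.3,0.793,0.104,4000000.0,
32,hepatic,30.0,6.6,0.286,0.0637,8000000.0,17912.763000000003
33,splenic,30.0,6.3,0.364,0.0702,8000000.0,14330.210400000002
34,superior_mesenteric,31.0,5.9,0.5655,0.0897,8000000.0,14330.210400000002
35,abdominal_aorta_b,31.0,1.0,0.78,0.104,4000000.0,
36,l_renal,35.0,3.2,0.338,0.0689,8000000.0,15922.456000000004
37,abdominal_aorta_c,35.0,1.0,0.767,0.104,4000000.0,
38,r_renal,37.0,3.2,0.338,0.0689,8000000.0,15922.456000000004
39,abdominal_aorta_d,37.0,10.6,0.754,0.104,4000000.0,
40,inferior_mesenteric,39.0,5.0,0.208,0.0559,8000000.0,47767.36800000001
41,abdominal_aorta_e,39.0,1.0,0.676,0.1014,4000000.0,
42,r_common_iliac,41.0,5.8,0.481,0.078,4000000.0,
43,l_common_iliac,41.0,5.8,0.481,0.078,4000000.0,
44,r_internal_iliac,42.0,5.0,0.26,0.052,16000000.0,47767.36800000001
45,r_external_iliac,42.0,14.4,0.416,0.0689,8000000.0,
46,l_internal_iliac,43.0,5.0,0.26,0.052,16000000.0,47767.36800000001
47,l_external_iliac,43.0,14.4,0.416,0.0689,8000000.0,
48,r_deep_femoral,45.0,12.6,0.3315,0.065,16000000.0,57320.84160000001
49,r_femoral,45.0,44.3,0.338,0.065,8000000.0,
50,l_deep_femoral,47.0,12.6,0.3315,0.065,16000000.0,57320.84160000001
51,l_femoral,47.0,44.3,0.338,0.065,8000000.0,
52,r_anterior_tibial,49.0,40.0,0.2066,0.0507,16000000.0,95534.73600000002
53,r_posterior_tibial,49.0,38.0,0.286,0.0585,16000000.0,57320.84160000001
54,l_anterior_tibial,51.0,40.0,0.2066,0.0507,16000000.0,95534.73600000002
55,l_posterior_tibial,51.0,38.0,0.286,0.0585,16000000.0,57320.84160000001
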