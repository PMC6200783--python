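case_id,eye_index,laterality,sex,age,sct_um,flow_pct,sd_octa
1,1,OD,M,35,290,29.2,+
1,2,OS,M,35,269,30.4,+
2,3,OD,M,27,247,25.3,+
2,4,OS,M,27,430,34.7,-
3,5,OD,M,57,355,30.8,-
4,6,OD,M,39,344,37.9,+
4,7,OS,M,39,398,38.9,+
5,8,OD,M,30,301,29.5,+
5,9,OS,M,30,290,27.4,+
6,10,OD,F,31,312,22.1,+
7,11,OD,M,67,269,17.2,-
7,12,OS,M,67,237,13.8,-
8,13,OD,M,43,430,50.1,+
9,14,OD,M,34,366,28.6,+
10,15,OD,F,55,258,21.8,-
11,16,OS,F,30,260,21.3,+
12,17,OD,F,43,180,11.5,+
13,18,OD,F,39,290,23.0,-
14,19,OD,M,38,300,18.5,-
14,20,OS,M,38,260,25.8,-
15,21,OD,M,42,340,32.6,-
16,22,OD,F,31,380,38.2,-
16,23,OS,F,31,410,39.9,-
17,24,OS,F,39,260,20.6,+
18,25,OD,F,28,250,21.3,+
18,26,OS,F,28,250,20.9,+
19,27,OD,F,34,300,27.5,-
19,28,OS,F,34,340,26.9,-
20,29,OD,F,35,220,22.0,-
20,30,OS,F,35,220,19.9,-
21,31,OD,F,45,200,15.8,+
22,32,OS,F,45,280,19.3,-
23,33,OD,F,41,270,25.2,+
23,34,OS,F,41,280,24.7,+
24,35,OD,F,28,290,27.6,-
24,36,OS,F,28,340,21.7,-
25,37,OS,M,45,280,32.6,+
26,38,OS,F,30,280,19.3,+
27,39,OS,M,32,320,28.9,+
28,40,OS,M,44,200,13.7,+
29,41,OD,F,42,320,25.0,-
30,42,OD,F,38,260,28.3,+
31,43,OS,F,26,280,30.0,-
32,44,OD,F,37,260,22.9,+
32,45,OS,F,37,300,24.5,+
33,46,OD,F,45,240,19.4,-
34,47,OD,F,43,240,17.4,+
35,48,OD,M,35,260,27.8,-
35,49,OS,M,35,260,29.3,-
36,50,OD,F,38,300,27.0,-
36,51,OS,F,38,300,26.1,-
37,52,OD,F,36,280,27.4,+
37,53,OS,F,36,300,29.7,+
38,54,OD,F,32,500,45.1,+
39,55,OD,M,42,300,35.8,+
40,56,OS,M,38,400,40.6,+
41,57,OD,M,40,300,34.1,-
42,58,OS,F,40,400,48.8,+
43,59,OS,F,46,260,21.9,+
44,60,OS,M,36,260,31.2,+
45,61,OD,M,32,360,38.3,-
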