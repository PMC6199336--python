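patient_no,gender,age,disease_duration_y,dominant_side,hoehn_yahr,updrs_motor,ace_r,mmse,lde
1,M,63,11,R,1.5,16,94,29,1315
2,M,74,15,L,2,19,98,30,620
3,M,81,15,L,2.5,20,94,29,410
4,M,54,15,L,1,26,89,29,1815
5,M,56,11,R,3,14,86,29,1210
6,F,73,13,B,2.5,13,95,28,565
7,F,76,9,R,3,13,91,30,855
8,F,81,13,L,2,16,97,29,1355
9,M,77,13,L,2,37,97,30,1720
10,M,64,6,L,1.5,15,94,29,1175
11,M,48,6,R,2.5,24,88,29,535
12,M,72,26,L,1,21,85,28,460
13,M,57,14,B,1,21,94,28,1180
14,F,66,17,L,2,21,95,27,1740
15,M,76,12,L,1,31,87,27,1500
16,F,64,11,B,3,19,96,28,1000
17,M,77,9,L,3,18,88,27,700
18,F,55,8,L,2,16,98,29,200
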