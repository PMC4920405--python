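# Gammarus pulex exposed to diazinon
C1:102.65,97.59,0,0,103.88,98.19,0,0,0,0
C2:100.78,106.32,0,0,103.56,95.82,0,0,0
C3:100.6,94.61,0,0,100.58,96.51,0,9.85
Ct1:0,1.02,1.03,2.99,3.01,4.01,4.02,11.01,18.01,22.01
Ct2:0,1.02,1.03,8,8.01,9,9.01,15,22.01
Ct3:0,1.02,1.03,16,16.01,17,17.01,22.01
y1:70,66,61,55,31,31,29,26,24,22,21,19,17,14,14,13,11,11,10,9,8,8,8
y2:70,65,59,56,54,50,47,46,46,40,23,22,22,21,18,17,17,13,13,13,11,11,11
y3:70,65,59,55,53,51,48,46,46,46,44,41,40,40,40,39,38,36,33,28,24,23,19
yt1:0,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22
yt2:0,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22
yt3:0,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22
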