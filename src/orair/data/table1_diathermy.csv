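timestamp,b05_1,b1_2,b2_3,b3_5,b5_10,b10p
15:18:33,34,19,8,3,0,0
15:18:38,68,31,13,3,0,0
15:18:43,73,34,13,2,0,0
15:18:48,111,49,11,1,0,1
15:18:53,100,47,20,6,0,0
15:18:58,92,36,11,3,0,0
15:19:03,104,48,17,3,0,0
15:19:08,109,41,11,5,3,0
15:19:13,84,34,13,2,3,0
15:19:18,76,33,7,4,0,0
15:19:23,87,34,8,3,2,0
15:19:28,77,30,11,3,0,0
15:19:33,86,30,13,2,2,0
15:19:38,60,29,9,0,0,0
15:19:43,63,21,5,2,0,0
15:19:48,56,28,5,4,1,0
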