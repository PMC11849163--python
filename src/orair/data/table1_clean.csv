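timestamp,b05_1,b1_2,b2_3,b3_5,b5_10,b10p
15:42:48,1,1,0,0,0,0
15:42:53,0,0,0,0,0,0
15:42:58,0,0,0,0,0,0
15:43:03,1,1,0,0,0,0
15:43:08,0,0,1,1,0,0
15:43:13,0,0,0,0,0,0
15:43:18,0,0,0,0,0,0
15:43:23,0,0,0,1,0,0
15:43:28,2,1,0,0,0,0
15:43:33,0,0,0,0,1,1
15:43:38,0,0,0,0,0,0
15:43:43,0,0,0,0,1,0
15:43:48,0,0,0,1,0,0
15:43:53,0,0,1,0,0,0
15:43:58,0,0,0,0,0,0
15:44:03,0,0,0,0,0,0
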