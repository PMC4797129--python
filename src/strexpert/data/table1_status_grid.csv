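replicate,blood_fta,blood_untreated,buccal_fta,buccal_untreated
1,Y,Y,Y,Y
2,Y,Y*,Y,Y
3,Y,Y,Y,Y
4,Y,Y,Y,Y
5,Y,Y,Y,Y*
6,Y,Y,Y,Y
7,Y,Y,Y,Y
8,Y,Y,Y,Y
9,Y,Y,Y,Y
10,Y,Y,Y,Y
11,Y,Y,Y,Y
12,Y,Y,Y,Y
13,Y,Y,Y,Y
14,Y,Y,Y,Y
15,Y,Y,Y,Y
16,Y,Y,Y,Y
17,Y,Y,Y,Y
18,Y,Y,Y,Y
19,Y,Y,Y,Y
20,Y,Y,Y,Y
21,Y*,Y,F,Y
22,Y,Y,Y,Y
23,Y,Y,Y,Y*
24,Y,Y,Y,Y
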