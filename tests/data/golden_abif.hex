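414249460065746469720000000103ff001c00000007000000c4000000b30000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000000000000000000000000000000000000000000000000000000000000
0000000a006403e80064000a0000fffd00050006000700080009000a000b000c
06676f6c64656e73616d706c65006d696e690044415441000000010004000200
0000080000001000000080000000004441544100000002000400020000000800
00001000000090000000004479654e0000000100120001000000030000000302
464c00000000004479654e00000002001200010000000400000004034a4f4500
000000534d504c00000001001200010000000700000007000000a00000000052
756e4b00000001001300010000000700000007000000a70000000050616e4900
000001001300010000000500000005000000ae00000000
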