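peak_id	rt_min	precursor_mz	ions_seen	fragments
1	29.8	959.4833	[M+Na]+;[M+H-H2O]+	919, 757, 595, 433, 415, 271, 253
2	31.7	941.4726	[M+Na]+;[M+H-H2O]+	901, 739, 577, 415, 273, 255
3	37.6	943.4886	[M+Na]+;[M+H-H2O]+	903, 741, 579, 417, 273, 255
4	38.5	943.4882	[M+Na]+;[M+H-H2O]+	903, 741, 579, 417, 273, 255
5	39.2	943.4871	[M+Na]+;[M+H-H2O]+	903, 741, 579, 417, 273, 255
6	54.9	925.4788	[M+Na]+;[M+H]+	741, 579, 417, 273, 255
7	56.7	779.4202	[M+Na]+;[M+H-H2O]+	739, 595, 433, 415, 273, 255
8	57.6	781.4367	[M+Na]+;[M+H-H2O]+	741, 579, 417, 399, 271, 253
9	58.0	779.4189	[M+Na]+;[M+H-H2O]+	739, 577, 415, 273, 255
10	58.6	779.4184	[M+Na]+;[M+H-H2O]+	739, 595, 433, 415, 271, 253
11	60.4	779.4187	[M+Na]+;[M+H]+	757, 595, 433, 415, 271, 253
12	62.2	763.4237	[M+Na]+;[M+H]+	579, 417, 273, 255
13	63.9	763.4241	[M+Na]+;[M+H]+	579, 417, 273, 255
14	64.4	763.4221	[M+Na]+;[M+H]+	579, 417, 273, 255
15	75.8	601.3703	[M+Na]+;[M+H]+	417, 273, 255
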