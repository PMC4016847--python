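# Reference annotation table for the 60% ethanol fraction (15 saponins).
# theoretical_mz / experimental_mz are [M+Na]+ values at 4 dp; error_ppm at 1 dp.
peak_id	rt_min	formula	selected_ion	theoretical_mz	experimental_mz	error_ppm	fragments	identification
1	29.8	C45H76O20	[M+Na]+	959.4822	959.4833	-1.1	919, 757, 595, 433, 415, 271, 253	Timosaponin N
2	31.7	C45H74O19	[M+Na]+	941.4717	941.4726	-1.0	901, 739, 577, 415, 273, 255	Timosaponin M
3	37.6	C45H76O19	[M+Na]+	943.4873	943.4886	-1.4	903, 741, 579, 417, 273, 255	Timosaponin BII
4	38.5	C45H76O19	[M+Na]+	943.4873	943.4882	-1.0	903, 741, 579, 417, 273, 255	25R-Timosaponin BII
5	39.2	C45H76O19	[M+Na]+	943.4873	943.4871	0.2	903, 741, 579, 417, 273, 255	25S-Officinalisnin-I
6	54.9	C45H74O18	[M+Na]+	925.4767	925.4788	-2.3	741, 579, 417, 273, 255	Timosaponin BIII
7	56.7	C39H64O14	[M+Na]+	779.4188	779.4202	-1.8	739, 595, 433, 415, 273, 255	Timosaponin G
8	57.6	C39H66O14	[M+Na]+	781.4345	781.4367	-2.8	741, 579, 417, 399, 271, 253	Anemarrhena saponin I
9	58.0	C39H64O14	[M+Na]+	779.4188	779.4189	-0.1	739, 577, 415, 273, 255	Isomer of timosaponin G
10	58.6	C39H64O14	[M+Na]+	779.4188	779.4184	0.5	739, 595, 433, 415, 271, 253	25(27)-ene-Anemarrhena saponin I
11	60.4	C39H64O14	[M+Na]+	779.4188	779.4187	0.1	757, 595, 433, 415, 271, 253	Timosaponin A2
12	62.2	C39H64O13	[M+Na]+	763.4239	763.4237	0.3	579, 417, 273, 255	Timosaponin AIV
13	63.9	C39H64O13	[M+Na]+	763.4239	763.4241	-0.3	579, 417, 273, 255	Timosaponin AIII
14	64.4	C39H64O13	[M+Na]+	763.4239	763.4221	2.4	579, 417, 273, 255	25R-Timosaponin AIII
15	75.8	C33H54O8	[M+Na]+	601.3711	601.3703	1.3	417, 273, 255	Timosaponin AI
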