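# Percent cholinesterase inhibition of isolated compounds (0.1 mg/mL), mean ± SEM, n >= 3.
# ND = not detected. Reference inhibitor donepezil: AChE 98.2 ± 0.8, BuChE 79.8 ± 0.7.
compound	role	ache_mean	ache_sem	buche_mean	buche_sem
1	sample	17.9	0.3	37.6	0.6
2	sample	15.2	0.2	28.1	0.4
3	sample	12.5	0.4	75.8	0.7
4	sample	ND	ND	ND	ND
5	sample	14.1	0.3	35.3	0.5
6	sample	17.9	0.2	36.0	0.4
7	sample	14.2	0.5	0.6	0.1
8	sample	ND	ND	ND	ND
9	sample	ND	ND	ND	ND
10	sample	0.9	0.1	0.1	0.1
11	sample	7.9	0.3	4.0	0.2
12	sample	1.7	0.2	15.1	0.3
13	sample	18.5	0.4	0.5	0.1
14	sample	27.2	0.2	4.2	0.2
15	sample	21.6	0.4	ND	ND
16	sample	1.1	0.1	ND	ND
17	sample	13.2	0.3	ND	ND
18	sample	15.9	0.4	ND	ND
19	sample	23.5	0.4	12.3	0.6
20	sample	18.4	0.4	ND	ND
21	sample	19.2	0.3	ND	ND
22	sample	17.3	0.3	ND	ND
23	sample	20.3	0.5	7.3	0.2
24	sample	21.1	0.6	ND	ND
25	sample	22.4	0.2	2.8	0.2
Donepezil	reference	98.2	0.8	79.8	0.7
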