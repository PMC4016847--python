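# Percent cholinesterase inhibition of crude extracts (1 mg/mL), mean ± SEM, n >= 3.
# ND = not detected. Reference inhibitor donepezil: AChE 98.0 ± 0.5, BuChE 80.2 ± 0.6.
solvent	technique	ache_mean	ache_sem	buche_mean	buche_sem
Petroleum ether	ultrasonic	ND	ND	ND	ND
Petroleum ether	heat reflux	ND	ND	ND	ND
Petroleum ether	cold soak	ND	ND	1.6	0.1
Dichloromethane	ultrasonic	ND	ND	41.5	0.5
Dichloromethane	heat reflux	ND	ND	15.7	0.7
Dichloromethane	cold soak	ND	ND	41.2	0.6
Ethyl acetate	ultrasonic	ND	ND	44.1	0.5
Ethyl acetate	heat reflux	ND	ND	27.7	0.4
Ethyl acetate	cold soak	ND	ND	40.8	0.8
Acetone	ultrasonic	ND	ND	38.8	0.3
Acetone	heat reflux	ND	ND	22.2	0.3
Acetone	cold soak	ND	ND	37.9	0.7
Methanol	ultrasonic	ND	ND	12.3	0.4
Methanol	heat reflux	ND	ND	5.4	0.2
Methanol	cold soak	ND	ND	7.1	0.3
95% ethanol	ultrasonic	ND	ND	4.9	0.2
95% ethanol	heat reflux	ND	ND	2.8	0.1
95% ethanol	cold soak	ND	ND	3.9	0.3
70% ethanol	ultrasonic	ND	ND	1.8	0.1
70% ethanol	heat reflux	ND	ND	ND	ND
70% ethanol	cold soak	ND	ND	1.6	0.2
50% ethanol	ultrasonic	ND	ND	2.8	0.1
50% ethanol	heat reflux	ND	ND	ND	ND
50% ethanol	cold soak	ND	ND	0.5	0.1
30% ethanol	ultrasonic	ND	ND	2.4	0.1
30% ethanol	heat reflux	ND	ND	ND	ND
30% ethanol	cold soak	ND	ND	1.8	0.2
Water	ultrasonic	ND	ND	ND	ND
Water	heat reflux	ND	ND	ND	ND
Water	cold soak	ND	ND	ND	ND
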