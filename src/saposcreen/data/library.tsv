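name	is_standard	skeleton	c22_hydroxyl	extra_aglycone_oh	ene_25_27	n_hexose	c25_config	aglycone_formula	sugar_labels	dehydration	root_listed	ering_loss	extra_h2o_branch	rt_ref
Timosaponin N	0	furostanol	1	1	0	3	unspecified	C27H46O5	Gal,Glc,Glc	early	1	auto	0	29.8
Timosaponin M	0	furostanol	1	0	1	3	unspecified	C27H44O4	Gal,Glc,Glc	early	1	auto	0	31.7
Timosaponin BII	1	furostanol	1	0	0	3	S	C27H46O4	Gal,Glc,Glc	early	1	auto	0	37.6
25R-Timosaponin BII	0	furostanol	1	0	0	3	R	C27H46O4	Gal,Glc,Glc	early	1	auto	0	38.5
25S-Officinalisnin-I	0	furostanol	1	0	0	3	S	C27H46O4	Gal,Glc,Glc	early	1	auto	0	39.2
Timosaponin BIII	1	spirostanol	0	0	0	3	S	C27H44O3	Gal,Glc,Glc	none	0	auto	0	54.9
Timosaponin G	1	furostanol	1	0	1	2	unspecified	C27H44O4	Gal,Glc	late	1	auto	0	56.7
Anemarrhena saponin I	1	furostanol	1	0	0	2	unspecified	C27H46O4	Gal,Glc	early	1	C8H18O2	1	57.6
Isomer of timosaponin G	0	furostanol	1	0	1	2	unspecified	C27H44O4	Gal,Glc	early	1	auto	0	58.0
25(27)-ene-Anemarrhena saponin I	0	furostanol	1	0	1	2	unspecified	C27H44O4	Gal,Glc	late	1	C8H16O2	0	58.6
Timosaponin A2	0	spirostanol	0	1	0	2	unspecified	C27H44O4	Gal,Glc	none	1	auto	0	60.4
Timosaponin AIV	1	spirostanol	0	0	0	2	S	C27H44O3	Gal,Glc	none	0	auto	0	62.2
Timosaponin AIII	1	spirostanol	0	0	0	2	S	C27H44O3	Gal,Glc	none	0	auto	0	63.9
25R-Timosaponin AIII	0	spirostanol	0	0	0	2	R	C27H44O3	Gal,Glc	none	0	auto	0	64.4
Timosaponin AI	0	spirostanol	0	0	0	1	unspecified	C27H44O3	Glc	none	0	auto	0	75.8
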