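sample_id	role	isolate	replicate
iso_1_r1	culture	iso_1	1
iso_1_r2	culture	iso_1	2
iso_1_r3	culture	iso_1	3
iso_2_r1	culture	iso_2	1
iso_2_r2	culture	iso_2	2
iso_2_r3	culture	iso_2	3
ctrl_r1	uninoculated_control		1
ctrl_r2	uninoculated_control		2
ctrl_r3	uninoculated_control		3
blank_r1	extraction_blank		1
blank_r2	extraction_blank		2
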