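domain_name	rp_name	profile_accession
Ribosomal_S21	bS21	PF01165
Ribosomal_S30	eS30	PF04758
Ribosomal_S30AE	HPF	PF02482
Ribosomal_L9_N	bL9	PF01281
Ribosomal_L12	bL12	PF00542
Ribosomal_L31	bL31	PF01197
Ribosomal_L33	bL33	PF00471
Ribosomal_S6	bS6	PF01250
Ribosomal_S9	uS9	PF00380
Ribosomal_S15	uS15	PF00312
Ribosomal_S21e	eS21	PF01249
Ribosomal_L10	uL10	PF00466
Ribosomal_L11	uL11	PF00298
Ribosomal_L11_N	uL11	PF03946
S1	bS1	PF00575
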