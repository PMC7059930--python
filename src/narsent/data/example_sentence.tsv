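utterance_index	surface	lemma	msd_tag	probability	sense_id
0	Ala	Ala	subst:sg:nom:f	0.89
0	ma	mieć	fin:sg:ter:imperf	1.0
0	radosny	radosny	adj:sg:acc:m3:pos	1.0
0	nastrój	nastrój	subst:sg:nom.acc:m3	1.0
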