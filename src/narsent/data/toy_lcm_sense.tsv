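mieć	1	SV
myśleć	1	SV
kopać	1	DAV
pomagać	1	IAV
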