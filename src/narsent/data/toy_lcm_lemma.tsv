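mieć	SV
myśleć	SV
wiedzieć	SV
lubić	SV
rozumieć	SV
podziwiać	SV
kopać	DAV
biec	DAV
skakać	DAV
lecieć	DAV
machać	DAV
pomagać	IAV
oszukiwać	IAV
chwalić	IAV
dokuczać	IAV
zachęcać	IAV
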