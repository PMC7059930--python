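radosny	positive
wesoły	positive
piękny	positive
miły	positive
dobry	positive
smutny	negative
zły	negative
straszny	negative
brzydki	negative
ból	negative
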