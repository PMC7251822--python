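disease	0.3
ill	0.3
painful	0.3
nauseous	0.3
help	-0.3
remarkable	-0.3
waiting	-0.3
complicated	-0.3
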