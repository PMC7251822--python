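very	1.3
extremely	1.5
really	1.3
incredibly	1.7
highly	1.4
too	1.2
quite	1.1
somewhat	0.8
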