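Family	Individual	Variant	Status
49	P	MSH3:c.199_207del9	carrier
49	M	MSH3:c.199_207del9	carrier
49	U	MSH3:c.199_207del9	carrier
49	A	MSH3:c.199_207del9	carrier
49	GM	MSH3:c.199_207del9	carrier
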