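insilico	pcr	count
polymorphic	polymorphic	22
polymorphic	monomorphic	8
monomorphic	polymorphic	1
monomorphic	monomorphic	7
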