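category	count
deletions_at_homopolymers	2011
insertions_at_homopolymers	161
transitions	112
transversions	46
insertions_at_microsatellites	86
deletions_at_microsatellites	60
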