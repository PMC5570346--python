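protein	segment_a_start	segment_a_end	segment_b_start	segment_b_end
PGM3	54	114	115	169
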