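sample_type	bird_in_diet	n
feces	ambiguous	12
feces	no	9
feces	yes	7
stomach	ambiguous	8
stomach	no	2
stomach	yes	13
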