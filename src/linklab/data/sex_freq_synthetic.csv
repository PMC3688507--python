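value,frequency
M,0.492
F,0.508
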