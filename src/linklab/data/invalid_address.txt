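NO FIXED ADDRESS
UNKNOWN
NOT STATED
N/A
HOMELESS
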