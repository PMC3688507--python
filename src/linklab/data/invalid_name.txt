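UNKNOWN
NOT STATED
N/A
NO NAME
BABY OF *
TWIN * OF *
INFANT OF *
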