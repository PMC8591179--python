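condition,intratumoral,clear
Unguided,17,65
AR,8,77
IN,1,83
AR+IN,0,84
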