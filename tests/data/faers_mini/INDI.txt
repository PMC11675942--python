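primaryid$indi_pt
2001$Diabetes mellitus
3001$Weight decreased
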