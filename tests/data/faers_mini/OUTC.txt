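primaryid$outc_cod
2001$HO
2001$DE
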