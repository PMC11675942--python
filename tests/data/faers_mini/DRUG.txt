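primaryid$drug_seq$role_cod$drugname
1001$1$PS$BYETTA
10012$1$PS$BYETTA
2001$1$PS$OZEMPIC
3001$1$PS$Victoza
4001$1$PS$TRULICITY
4001$2$SS$METFORMIN
5001$1$C$byetta
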