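primaryid$pt
1001$Nausea
1001$Vomiting
10012$Nausea
2001$Pancreatitis
3001$Constipation
4001$Diarrhea
4001$Nausea
4001$Abdominal pain
5001$Nausea
9999$Nausea
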