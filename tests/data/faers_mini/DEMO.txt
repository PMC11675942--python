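primaryid$caseid$caseversion$age$age_cod$sex$occp_cod$reporter_country$fda_dt
1001$C1$1$55$YR$F$CN$US$20190315
10012$C1$2$55$YR$F$CN$US$20190520
2001$C2$1$660$MON$M$MD$US$20200101
3001$C3$1$61$YR$F$CN$CA$20180601
4001$C4$1$$$$OT$US$20210401
5001$C5$1$45$YR$M$CN$US$20170101
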