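##gff-version 3
Chr18	sdrase	gene	16275593	16279859	.	-	.	ID=PtStettler14.18G127900;Name=TCP
Chr18	sdrase	gene	16268169	16272894	.	-	.	ID=PtStettler14.18G127800;Name=CLC
Chr18	sdrase	gene	16249745	16259190	.	-	.	ID=PtStettler14.18G127700;Name=MET1
Chr18	sdrase	gene	16226313	16236215	.	-	.	ID=PtStettler14.18G127600;Name=NB-ARC
Chr18	sdrase	gene	16214199	16215600	.	+	.	ID=PtStettler14.18G127500;Name=unknown
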