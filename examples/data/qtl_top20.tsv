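QTL_ID	DE_lncRNAs	Chrome	Trait	Name	Start	End	Score
31542	3	14	Arachidonic acid content	FA-C20:4	138365048	138414114	6.11E-05
658	1	10	Average backfat thickness	BFT	11227321	11306620	1.26E-05
12712	1	1	Abdominal fat weight	ABDF	294607712	294736101	7.79E-06
21436	1	16	Loin fat percentage	LOINFP	83843383	84125107	3.55E-06
735	1	1	Average backfat thickness	BFT	307398864	307784034	2.60E-06
17773	1	1	Average backfat thickness	BFT	140716292	141412550	1.44E-06
12713	1	1	Abdominal fat weight	ABDF	245011782	245777288	1.31E-06
22290	1	X	Average backfat thickness	BFT	113078996	113962590	1.13E-06
736	1	4	Average backfat thickness	BFT	140987596	142372300	7.22E-07
7293	3	4	Abdominal fat percentage	ABDFP	81983315	87016757	5.96E-07
22480	2	5	Arachidic acid content	FA-C20:0	56004411	59682626	5.44E-07
22509	1	10	Arachidic acid content	FA-C20:0	56004411	59682626	2.72E-07
5435	1	10	Average backfat thickness	BFT	28168636	32088890	2.55E-07
3000	2	10	Average backfat thickness	BFT	32088890	41334738	2.16E-07
7530	1	3	Average backfat thickness	BFT	122295139	126926633	2.16E-07
18001	1	9	Average backfat thickness	BFT	145703416	151394450	1.76E-07
17803	1	8	Average backfat thickness	BFT	811090	6651169	1.71E-07
23307	1	6	Backfat at rump	BFTR	152297333	158443390	1.63E-07
849	1	1	Abdominal fat weight	ABDF	226764071	233806417	1.42E-07
2923	1	13	Average backfat thickness	BFT	208227233	215641489	1.35E-07
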