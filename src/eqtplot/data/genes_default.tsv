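Gene	CHR	Start	Stop	Build
ZDHHC24	11	66244086	66246542	hg19
DPP3	11	66247662	66276499	hg19
BBS1	11	66278077	66301084	hg19
ACTN3	11	66313866	66330849	hg19
CTSF	11	66330585	66336056	hg19
CCDC87	11	66339572	66341851	hg19
RAD9A	11	67159902	67184457	hg19
PPP1CA	11	67165553	67169843	hg19
CARNS1	11	67180896	67195980	hg19
PCSK9	1	55505221	55530525	hg19
SORT1	1	109852192	109940563	hg19
APOE	19	45409039	45412650	hg19
LDLR	19	11200038	11244505	hg19
ZDHHC24	11	66476655	66479111	hg38
DPP3	11	66480231	66509068	hg38
BBS1	11	66510646	66533614	hg38
ACTN3	11	66546395	66563329	hg38
CTSF	11	66563154	66568625	hg38
CCDC87	11	66572141	66574420	hg38
RAD9A	11	67392431	67416986	hg38
PPP1CA	11	67398082	67402372	hg38
CARNS1	11	67413425	67428509	hg38
PCSK9	1	55039548	55064852	hg38
SORT1	1	109309567	109397938	hg38
APOE	19	44905796	44909407	hg38
LDLR	19	11089362	11133829	hg38
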