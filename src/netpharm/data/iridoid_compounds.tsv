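# The 12 active iridoid glycosides of Eucommia ulmoides Oliver (metadata fixture)
no	compound	cas	formula	mol_weight
1	aucubin	479-98-1	C15H22O9	346.33
2	catalpol	2415-24-9	C15H22O10	362.33
3	ajugoside	52916-96-8	C17H26O10	390.4
4	asperuloside	14259-45-1	C18H22O11	414.4
5	asperulosidic acid	25368-11-0	C18H24O12	432.4
6	deacetyl asperulosidic acid	14259-55-3	C16H22O11	390.34
7	geniposide	24512-63-8	C17H24O10	388.4
8	geniposidic acid	27741-01-1	C16H22O10	374.34
9	reptoside	53839-03-5	C17H26O10	390.4
10	daphylloside	14260-99-2	C19H26O12	446.4
11	scandoside methyl ester	27530-67-2	C17H24O11	404.4
12	loganin	18524-94-2	C17H26O10	390.4
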