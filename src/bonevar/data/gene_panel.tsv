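symbol	inheritance	chrom	start	end	af_cutoff	is_x_linked
COL1A1	dominant	17	48260650	48278993		0
COL1A2	dominant	7	94023873	94060544		0
IFITM5	dominant	11	299496	300887		0
SGMS2	dominant	4	108746121	108833206		0
P4HB	dominant	17	79801034	79818587		0
LRP5	dominant	11	68080077	68216743		0
WNT1	dominant	12	49372572	49376398		0
PLS3	dominant	X	114795465	114885190		1
CLCN7	dominant	16	1496046	1526152		0
PLEKHM1	dominant	17	43513266	43568146		0
TNFRSF11A	dominant	18	59992449	60058515		0
ALPL	dominant	1	21835858	21904905		0
PHEX	dominant	X	22051479	22269547		1
DKK1	dominant	10	54074056	54077416		0
WNT3A	dominant	1	228194448	228248818		0
TCIRG1	recessive	11	67806077	67818324		0
TENT5A	recessive	6	82454549	82516862		0
BMP1	recessive	8	22022808	22069131		0
CREB3L1	recessive	11	46299244	46342972		0
SERPINH1	recessive	11	75273101	75283857		0
LEPRE1	recessive	1	43212006	43232755		0
PLOD2	recessive	3	145787328	145878955		0
CRTAP	recessive	3	33155467	33189682		0
PPIB	recessive	15	64448968	64456283		0
FKBP10	recessive	17	39968995	39979473		0
SP7	recessive	12	53720359	53739810		0
TMEM38B	recessive	9	108455830	108527331		0
SPARC	recessive	5	151040657	151066726		0
MESD	recessive	15	81296128	81316167		0
KDELR2	recessive	7	6486527	6525461		0
CCDC134	recessive	22	42196806	42222537		0
OSTM1	recessive	6	108362570	108395922		0
SNX10	recessive	7	26331867	26413943		0
TNFSF11	recessive	13	43148293	43182149		0
CTSK	recessive	1	150768683	150780915		0
DMP1	recessive	4	88583454	88597759		0
ENPP1	recessive	6	132129154	132216295		0
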