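gene	mutation_id	coordinate	change	effect	frequency_pct	first_timepoint
IS1	IS1	257908	G -> A	IS1 non-coding	5	T5
frmR	frmR_1	379625	A -> C	V(86) -> G	5	T7
frmR	frmR_2	379821	-1:C	Q(21) -> frameshift	5	T7
gltA	gltA	754123	C -> T	E(116) -> K	10	T4
plsX	plsX_1	1148440	-1:A	Q(274)KS -> QRA STOP	10	T3
plsX	plsX_2	1148491	G -> T	G(291) -> C	10	T4
fabF	fabF_1	1152159	T -> G	F(74) -> C	48	T3
fabF	fabF_2	1152159	C -> T	wt	5	T4
marC	marC_1	1618245	A -> T	stop -> frameshift	10	T4
marC	marC_2	1618498	-7:ATCGCTA	I(135) -> stop	10	T2
marC	marC_3	1618805	-1:T	M(35) -> stop	48	T3
yffS	yffS	2564930	G -> T	A -> A (silent)	5	T3
yfgO	yfgO	2615421	G -> A	A(154) -> V	5	T2
iscR	iscR	2661812	T -> A	H(107) -> L	10	T5
srmB	srmB	2713364	G -> A	D(157) -> N	10	T2
P_yghB	P_yghB	3153480	-15	15-bp promoter deletion over the -35 region	33	T4
trkH	trkH	4033611	G -> A	G(156) -> D	10	T5
rraA	rraA_1	4119044	A -> T	V(96) -> E	10	T4
rraA	rraA_2	4119138	C -> T	G(67) -> S	5	T4
plsB	plsB	4255502	T -> C	Q(322) -> R	5	T2
rob	rob_1	4634494	C -> A	G(273) -> stop	5	T5
rob	rob_2	4635002	+1:T	Y(103) -> stop	10	T6
rob	rob_3	4635168	+1:G	H(48) -> frameshift	19	T6
creC	creC	4637267	T -> G	L(191) -> W	5	T5
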