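#class	subclass	superfamily	category	aliases
ClassI	nLTR	R2	LINE	r2
ClassI	nLTR	L1	LINE	l1,line-1,line1
ClassI	nLTR	CR1	LINE	cr1
ClassI	nLTR	Penelope	LINE	penelope,ple
ClassI	nLTR	MIR/MIR-core	SINE	mir,mir-core,mircore
ClassI	nLTR	tRNA-SINE	SINE	trna,sine,sine2
ClassI	LTR	Ty3/Gypsy	LTR	gypsy,ty3
ClassI	LTR	Ty1/Copia	LTR	copia,ty1
ClassI	LTR	ERV	LTR	erv,ervl,erv1
ClassI	LTR	DIRS	LTR	dirs
ClassII	Cryptons	CryptonA/Crypton-A	DNA	crypton,cryptona,crypton-a
ClassII	Helitrons	Helitron	DNA	helitron,rc
ClassII	DD (E/D) transposons	hAT	DNA	hat,hat-ac,hat-charlie,hat-tip100,charlie,tip100
ClassII	DD (E/D) transposons	PIF/Harbinger	DNA	harbinger,pif,pif-harbinger
ClassII	DD (E/D) transposons	Tc1/Mariner	DNA	tc1,mariner,tcmar,tc1-mariner
ClassII	DD (E/D) transposons	MITE	DNA	mite
ClassII	DD (E/D) transposons	nMITE	DNA	nmite
ClassII	DD (E/D) transposons	Kolobok	DNA	kolobok
Other	Simple_repeats	NA	non-TE	simple_repeat,simple_repeats,simple
Other	Low_complexity	NA	non-TE	low_complexity
Other	Satellites	NA	non-TE	satellite,satellites,sat
Other	rRNA	NA	non-TE	rrna
Other	tRNA_genes	NA	non-TE	trna_gene
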