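gene_id	symbol	category	length_aa
K02689	psaA	PSI	755
K02690	psaB	PSI	740
K02691	psaC	PSI	81
K02692	psaD	PSI	141
K02693	psaE	PSI	75
K02694	psaF	PSI	165
K02696	psaI	PSI	40
K02697	psaJ	PSI	42
K02698	psaK	PSI	86
K02699	psaL	PSI	157
K02700	psaM	PSI	31
K02703	psbA	PSII	360
K02704	psbB	PSII	507
K02705	psbC	PSII	461
K02706	psbD	PSII	352
K02707	psbE	PSII	83
K02708	psbF	PSII	44
K02709	psbH	PSII	64
K02710	psbI	PSII	38
K02711	psbJ	PSII	40
K02712	psbK	PSII	45
K02713	psbL	PSII	39
K02714	psbM	PSII	36
K02717	psbO	PSII	274
K02718	psbP	PSII	189
K02720	psbT	PSII	33
K02721	psbU	PSII	131
K02722	psbV	PSII	161
K02723	psbW	PSII	137
K02724	psbX	PSII	39
K02725	psbY	PSII	39
K02726	psbZ	PSII	62
K02634	petA	Cytb6f	320
K02635	petB	Cytb6f	215
K02636	petC	Cytb6f	179
K02637	petD	Cytb6f	160
K02640	petG	Cytb6f	37
K02642	petL	Cytb6f	32
K02643	petM	Cytb6f	33
K03689	petN	Cytb6f	29
K02638	petE	PET	105
K02639	petF	PET	98
K02641	petH	PET	402
K08906	petJ	PET	111
K02111	atpA	ATPase	502
K02112	atpD	ATPase	482
K02113	atpH	ATPase	181
K02114	atpC	ATPase	134
K02115	atpG	ATPase	315
K02108	atpB	ATPase	247
K02109	atpF	ATPase	171
K02110	atpE	ATPase	81
K02116	atpI	ATPase	126
K02092	apcA	PBS_APC	161
K02093	apcB	PBS_APC	161
K02094	apcC	PBS_APC	67
K02095	apcD	PBS_APC	161
K02096	apcE	PBS_APC	896
K02097	apcF	PBS_APC	169
K02284	cpcA	PBS_PC_PEC	162
K02285	cpcB	PBS_PC_PEC	172
K02286	cpcC	PBS_PC_PEC	291
K02287	cpcD	PBS_PC_PEC	80
K02288	cpcE	PBS_PC_PEC	260
K02289	cpcF	PBS_PC_PEC	205
K02290	pecA	PBS_PC_PEC	162
K02291	pecB	PBS_PC_PEC	172
K05376	cpeA	PBS_PE	164
K05377	cpeB	PBS_PE	177
K05378	cpeC	PBS_PE	289
K05379	cpeD	PBS_PE	251
K05380	cpeE	PBS_PE	244
K0209X2	apcD2	FaRLiP	161
K0209X3	apcD3	FaRLiP	161
K0209X5	apcD5	FaRLiP	161
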