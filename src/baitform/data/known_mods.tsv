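name	mono_mass	residues	provenance
carbamylation	43.00581	N-term,K,R	urea-induced artifact; Unimod 5
carbamidomethyl	57.02146	C	iodoacetamide alkylation; Unimod 4
oxidation	15.99491	M,C,W	Unimod 35
dioxidation (sulfinic acid)	31.98983	C	Unimod 425
trioxidation (cysteic acid)	47.98474	C	Unimod 345
phosphorylation	79.96633	S,T,Y	Unimod 21
acetylation	42.01057	K,N-term	Unimod 1
methylation	14.01565	K,R	Unimod 34
deamidation	0.98402	N,Q	Unimod 7
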