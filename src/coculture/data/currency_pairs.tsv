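metabolite_1	metabolite_2
atp	adp
atp	amp
nad	nadh
nadp	nadph
gtp	gdp
gdp	gmp
utp	udp
udp	ump
ctp	cdp
cdp	cmp
fad	fadh2
fmn	fmnh2
q8	q8h2
mqn8	mql8
glu_L	akg
gln_L	glu_L
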