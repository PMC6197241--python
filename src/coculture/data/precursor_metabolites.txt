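# The 13 central-carbon precursor metabolites (branch points from which
# biomass components derive), by compartment-stripped base id.
g6p
f6p
r5p
e4p
g3p
3pg
pep
pyr
accoa
akg
succoa
oaa
dhap
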