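# Highly connected (currency) metabolites removed from metabolite graphs,
# by compartment-stripped base id (AGORA/BiGG naming).
h
h2o
atp
adp
amp
nad
nadh
nadp
nadph
pi
ppi
coa
o2
nh4
h2o2
so4
so3
no2
no3
h2s
h2co3
no
s
fe2
fe3
cobalt2
hco3
h2
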