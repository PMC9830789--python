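# Invented term-like strings (no real patient-derived text).
flebargie
velatose
cardunitis
pneumalgie
dermatrofie
nefrolasie
hepatomie
gastrelose
artrovitis
osteoplasie
neuralgiet
myocardose
bronchiet
laryngofie
tracheose
oesofagiet
colonopame
splenargie
thyrotie
adenopame
lymfocelie
vasculiet
trombase
embolose
aneurose
stenalgie
fistulame
ulcerose
erytheem
purpurose
petechiame
exantheem
pruritase
alopecose
onychiet
keratose
scleriet
uveose
retinopame
glaucomie
cataralose
otalgiet
sinusopame
rhinargie
faryngose
tonsilliet
glossopame
stomatose
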