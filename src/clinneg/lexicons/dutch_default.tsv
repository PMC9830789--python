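# Illustrative Dutch trigger lexicon (ConText-style).
# Columns: pattern<TAB>category<TAB>max_scope (empty = sentence default)
# Categories: negation_forward, negation_backward, pseudo, termination
geen	negation_forward
niet	negation_forward
nooit	negation_forward
zonder	negation_forward
geen aanwijzing voor	negation_forward
geen aanwijzingen voor	negation_forward
geen tekenen van	negation_forward
geen teken van	negation_forward
geen sprake van	negation_forward
geen evidentie voor	negation_forward
geen argumenten voor	negation_forward
geen bewijs voor	negation_forward
negatief voor	negation_forward
vrij van	negation_forward
ontkent	negation_forward
uitsluiting van	negation_forward
pleit tegen	negation_forward
niet voorafgegaan door	negation_forward
uitgesloten	negation_backward
werd uitgesloten	negation_backward
niet aangetoond	negation_backward
niet aanwezig	negation_backward
afwezig	negation_backward
niet waarschijnlijk	negation_backward
werd niet gezien	negation_backward
is verdwenen	negation_backward
niet alleen	pseudo
niet uit te sluiten	pseudo
geen toename van	pseudo
niet zeker	pseudo
zonder twijfel	pseudo
niet duidelijk of	pseudo
maar	termination
echter	termination
behalve	termination
wel	termination
hoewel	termination
toch	termination
behoudens	termination
desondanks	termination
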