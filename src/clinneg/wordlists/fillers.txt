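# Function words and neutral filler vocabulary for synthetic sentences.
# Words also occurring in a trigger grammar are removed at generation time.
de
het
een
en
in
op
bij
aan
rond
onder
over
na
sinds
patient
vandaag
gisteren
controle
verder
beleid
rustig
stabiel
thuis
dag
week
maand
links
rechts
boven
beloop
herstel
goed
matig
licht
fors
beiderzijds
regio
status
anamnese
onderzoek
lab
echo
foto
consult
advies
retour
afspraak
poli
opname
ontslag
medicatie
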