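amazing	0.8
attentive	0.6
awful	-1.0
bad	-0.7
brilliant	0.9
calm	0.4
careful	0.5
caring	0.7
cheerful	0.6
clean	0.5
clear	0.4
cold	-0.5
comfortable	0.6
competent	0.6
complicated	0.4
confusing	-0.5
convenient	0.4
cosy	0.5
courteous	0.6
crowded	-0.4
delicious	0.8
dirty	-0.8
disappointing	-0.7
disease	-0.6
dreadful	-0.9
easy	0.5
efficient	0.6
excellent	1.0
expert	0.6
fantastic	0.9
fast	0.4
fine	0.3
friendly	0.7
frightening	-0.8
frustrating	-0.7
gentle	0.5
good	0.7
great	0.8
helpful	0.7
help	0.4
honest	0.5
horrible	-1.0
hot	-0.3
hygienic	0.5
ill	-0.6
impatient	-0.5
impersonal	-0.5
impolite	-0.6
inadequate	-0.6
inattentive	-0.5
incompetent	-0.8
inconvenient	-0.4
insecure	-0.5
kind	0.7
late	-0.4
loud	-0.4
lovely	0.8
messy	-0.5
modern	0.4
nauseous	-0.7
neat	0.4
nice	0.6
noisy	-0.6
okay	0.05
average	0.0
painful	-0.8
patient	0.4
perfect	1.0
pleasant	0.7
polite	0.6
poor	-0.6
professional	0.6
prompt	0.5
quick	0.4
quiet	0.4
remarkable	0.6
respectful	0.6
rude	-0.8
satisfied	0.6
slow	-0.4
sloppy	-0.6
smooth	0.5
spacious	0.4
stressful	-0.6
stuffy	-0.4
sweet	0.6
tasteless	-0.5
tasty	0.6
terrible	-1.0
thorough	0.5
tidy	0.4
uncomfortable	-0.6
unclear	-0.5
unfriendly	-0.7
unhelpful	-0.6
unpleasant	-0.7
unprofessional	-0.7
waiting	0.3
warm	0.5
welcoming	0.6
wonderful	0.9
wrong	-0.5
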