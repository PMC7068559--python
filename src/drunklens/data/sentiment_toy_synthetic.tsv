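# Synthetic 20-word toy positive-sentiment lexicon (word <tab> weight).
# Stands in for an external weighted sentiment lexicon; same two-column
# format, so a real lexicon file can be dropped in.
love	1.5
happy	1.2
great	1.0
fun	1.1
best	1.3
good	0.9
awesome	1.4
nice	0.7
amazing	1.4
cool	0.6
sweet	0.8
win	0.5
party	0.4
friend	0.3
smile	0.9
laugh	0.8
yay	1.0
woo	0.7
blessed	1.1
glad	0.8
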