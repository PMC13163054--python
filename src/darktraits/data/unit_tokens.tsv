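# Closed unit dialect table: token <TAB> kind <TAB> factor
# kinds: volume (factor -> mL), mass (factor -> kg), time (factor -> hours),
#        oxygen (marker, factor unused), temperature (offset handled in code).
# Tokens are matched case-insensitively after superscript/minus normalization;
# "cm3"/"mm3" are matched as the letter token with exponent 3.
# Edit or extend this file (and load it via units.load_unit_table) to teach
# the parser additional historical dialects; unknown tokens always raise.
ml	volume	1
cc	volume	1
cm3	volume	1
mm3	volume	0.001
l	volume	1000
mg	mass	1e-6
g	mass	1e-3
kg	mass	1
s	time	0.0002777777777777778
sec	time	0.0002777777777777778
min	time	0.016666666666666666
h	time	1
hr	time	1
hour	time	1
d	time	24
day	time	24
o2	oxygen	1
c	temperature	1
k	temperature	1
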