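protein	segment_label	start	end
Ara h 9	helix1	4	18
Ara h 9	loop12	19	25
Ara h 9	helix2	26	37
Ara h 9	loop23	38	44
Ara h 9	helix3	45	57
Ara h 9	loop34	58	62
Ara h 9	helix4	63	73
Ara h 9	cterm_coil	74	92
Jug r 3	helix1	5	19
Jug r 3	loop12	20	26
Jug r 3	helix2	27	38
Jug r 3	loop23	39	45
Jug r 3	helix3	46	58
Jug r 3	loop34	59	63
Jug r 3	helix4	64	74
Jug r 3	cterm_coil	75	94
Pru p 3	helix1	4	18
Pru p 3	loop12	19	25
Pru p 3	helix2	26	37
Pru p 3	loop23	38	44
Pru p 3	helix3	45	57
Pru p 3	loop34	58	62
Pru p 3	helix4	63	73
Pru p 3	cterm_coil	74	91
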