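motif	position	residues
Bw4	77	NDS
Bw4	78	L
Bw4	79	R
Bw4	80	TI
Bw4	81	AL
Bw4	82	L
Bw4	83	R
Bw6	77	S
Bw6	78	L
Bw6	79	R
Bw6	80	N
Bw6	81	L
Bw6	82	R
Bw6	83	G
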