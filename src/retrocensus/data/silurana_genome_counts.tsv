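family	type	GSM1	GSM2
Bel/Pao	Kobel	129	140
Bel/Pao	Hydra3.1	0	2
Ty1/Copia	Hydra1.1	6	8
Ty1/Copia	Mtanga	8	8
Ty3/Gypsy	Amn-san	749	805
Ty3/Gypsy	Cer	30	25
Ty3/Gypsy	Gmr	177	215
Ty3/Gypsy	Mag	65	102
Retroviridae	MuERV	2	1
Retroviridae	SnRV	7	11
Retroviridae	XEN1	7	12
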