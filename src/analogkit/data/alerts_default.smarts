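# Default undesired-substructure alerts (one "id<TAB>SMARTS" per line).
# A small curated reactive/promiscuous-group list in the PAINS spirit;
# swap in a full published set via config for production campaigns.
nitro	[N+](=O)[O-]
azide	[N-]=[N+]=N
peroxide	[OX2][OX2]
acyl_halide	C(=O)[F,Cl,Br,I]
sulfonyl_halide	S(=O)(=O)[F,Cl,Br,I]
aldehyde	[CX3H1](=O)[#6]
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
alkyl_halide_reactive	[CH2X4][Br,I]
isocyanate	N=C=O
thiocyanate	SC#N
hydrazine	[NX3][NX3]
quinone	O=C1C=CC(=O)C=C1
epoxide_aliphatic	C1OC1
disulfide	[SX2][SX2]
nitroso	[NX2]=O
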