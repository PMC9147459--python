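# REOS functional-group catalog: reactive, toxic and otherwise undesirable
# moieties (nitro groups, peroxides, triflates, aldehydes, acetals, Michael
# acceptors and other electrophiles).  Editable; format:
#   name  SMARTS  [max_count]
# max_count is the maximum allowed number of distinct matches (default 0).
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
peroxide	[OX2][OX2]
triflate	[OX2][SX4](=[OX1])(=[OX1])C(F)(F)F
aldehyde	[CX3H1](=O)[#6]
acetal	[CX4]([OX2][#6])([OX2][#6])
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
epoxide	[OX2r3]1[#6r3][#6r3]1
isocyanate	[NX2]=[CX2]=[OX1]
alkyl_halide	[CX4;!$(C(F)(F)F)][Cl,Br,I]
thiol	[SX2H]
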