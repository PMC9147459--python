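# PAINS (pan-assay interference) substructure catalog.
# Curated, editable reconstruction covering the classic promiscuity families:
# rhodanines, phenolic Mannich bases, hydroxyphenylhydrazones, alkylidene
# barbiturates, alkylidene five-membered heterocycles, 2,5-disubstituted
# N-aryl pyrroles, activated benzofurazans, 2-amino-3-carbonylthiophenes,
# catechols and quinones.  One family-representative SMARTS per line:
#   name  SMARTS  [max_count]
# max_count defaults to 0 (any match flags the compound).  Lines starting
# with '#' are comments.  Replace or extend this file to screen with a
# different published set.
rhodanine	[#16X2]1[#6](=[SX1])[#7][#6](=[OX1])[#6]1
phenolic_mannich_base	[OX2H]c1ccccc1[CH2][NX3]
hydroxyphenyl_hydrazone	[OX2H]c1ccc(cc1)[CX3H1]=[NX2][NX3]
alkylidene_barbiturate	[#6X3]1(=[#6X3])[#6](=[OX1])[#7][#6](=[OX1])[#7][#6]1=[OX1]
alkylidene_five_ring_het	[#6;!R]=[#6;R]1[#6;R](=[OX1])[#7,#8,#16;R]~[#6,#7;R]~[#6,#7,#8,#16;R]1
aralkyl_pyrrole	[#6]c1ccc([#6])n1-c1ccccc1
activated_benzofurazan	[O-][N+](=O)c1ccc2nonc2c1
amino_thiophene_carbonyl	[NX3H2]c1sccc1[CX3]=[OX1]
catechol	[OX2H]c1ccccc1[OX2H]
quinone_para	[#6]1(=[OX1])[#6]=[#6][#6](=[OX1])[#6]=[#6]1
quinone_ortho	[#6]1(=[OX1])[#6](=[OX1])[#6]=[#6][#6]=[#6]1
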