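# Curated drug-like test panel: 56 molecules spanning fragment-size
# (MW ~ 46) to PPI-inhibitor-size (MW ~ 700) chemistry and SlogP ~ -1..9,
# so every built-in filter has both passers and failers.
CCO ethanol
c1ccccc1 benzene
Cc1ccccc1 toluene
Oc1ccccc1 phenol
Nc1ccccc1 aniline
c1ccncc1 pyridine
C1CCCCC1 cyclohexane
NC(N)=O urea
NCC(=O)O glycine
NC(=O)c1ccccc1 benzamide
CC(=O)Nc1ccc(O)cc1 paracetamol
CC(=O)Oc1ccccc1C(=O)O aspirin
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
CN1CCCC1c1cccnc1 nicotine
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
COc1ccc2cc(ccc2c1)C(C)C(=O)O naproxen
CCOC(=O)c1ccc(N)cc1 benzocaine
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1 salbutamol
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1 atenolol
CC(C)NCC(O)COc1cccc2ccccc12 propranolol
CN(C)C(=N)NC(N)=N metformin
CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1 diazepam
OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O lorazepam
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O warfarin
CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1 ketoprofen
Cc1cc(no1)NS(=O)(=O)c1ccc(N)cc1 sulfamethoxazole
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC trimethoprim
CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12 chloroquine
Cc1ccc(cc1Nc1nccc(n1)-c1cccnc1)NC(=O)c1ccc(CN2CCN(C)CC2)cc1 imatinib
OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1 haloperidol
CN(C)CCC=C1c2ccccc2CCc2ccccc21 amitriptyline
CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1 fluoxetine
CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1 tamoxifen
CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12 simvastatin
CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O atorvastatin
CCC(C)N1N=CN(c2ccc(cc2)N2CCN(CC2)c2ccc(OCC3COC(Cn4cncn4)(O3)c3ccc(Cl)cc3Cl)cc2)C1=O itraconazole
CC(=O)N1CCN(CC1)c1ccc(OCC2COC(Cn3ccnc3)(O2)c3ccc(Cl)cc3Cl)cc1 ketoconazole
CC(C)CC(N(C)C(=O)C(C)NC(=O)C(C)N)C(=O)NC(C(C)C)C(=O)O peptide_fragment
CCC1OC(=O)C(C)C(O)C(C)C(O)C(C)(O)CC(C)C(=O)C(C)C(O)C1C macrolide_core
COc1cccc2C(=O)c3c(O)c4CC(O)(CC(OC5CC(N)C(O)C(C)O5)c4c(O)c3C(=O)c12)C(=O)CO doxorubicin
CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(/C=C/c2ccc3ccc(Cl)cc3n2)c1 montelukast
CCCc1nc2c(C)cc(-c3nc4ccccc4n3C)cc2n1Cc1ccc(-c2ccccc2C(=O)O)cc1 telmisartan
CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1 amiodarone
CC(C)N=C1C=C2N(c3ccc(Cl)cc3)c3ccccc3N=C2C=C1Nc1ccc(Cl)cc1 clofazimine
CS(=O)(=O)CCNCc1ccc(o1)-c1ccc2ncnc(Nc3ccc(OCc4cccc(F)c4)c(Cl)c3)c2c1 lapatinib
Cc1cn(cn1)-c1cc(NC(=O)c2ccc(C)c(Nc3nccc(n3)-c3cccnc3)c2)cc(c1)C(F)(F)F nilotinib
O=S(=O)(c1ccc(N2CCN(Cc3ccccc3-c3ccccc3)CC2)cc1)NC(=O)c1ccc(N2CCOCC2)cc1 biaryl_sulfonamide
CC1C=CC=C(C)C(=O)Nc2c(O)c3c(O)c(C)c(O)c(C(=O)C(C)C(O)C1C)c3c(O)c2C=NN1CCN(C)CC1 ansamycin_core
CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5 morphine
CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12 lovastatin
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O penicillin_g
OC(=O)CCC(=O)O succinic_acid
C1CNCCN1 piperazine
CCCCCC hexane
COc1ccc2CC3C4CCCCC4(CCN3C)c2c1 dextromethorphan
COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC verapamil
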