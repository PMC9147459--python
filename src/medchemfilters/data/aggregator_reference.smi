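# SYNTHETIC 20-molecule aggregator-reference fixture.
# Lipophilic, polycyclic structures of the kind enriched among colloidal
# aggregators (flavonoids, polyphenols, azole antifungals, dyes, steroids).
# This file is a stand-in for the external ~12,600-compound known-aggregator
# collection, which is not redistributed here; it claims no fidelity to it
# and exists so similarity-based classification is testable offline.
O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12 quercetin
O=c1cc(-c2ccccc2)oc2ccccc12 flavone
COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O curcumin
Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1 clotrimazole
Clc1ccc(C(Cn2ccnc2)OCc2ccc(Cl)cc2Cl)c(Cl)c1 miconazole_like
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1 resveratrol
CC(C)=CCc1c(O)cc(O)c2c1oc(-c1ccc(O)cc1)cc2=O prenyl_flavonoid
c1ccc2c(c1)ccc1ccccc12 phenanthrene
c1cc2ccc3cccc4ccc(c1)c2c34 pyrene
c1ccc2cc3ccccc3cc2c1 anthracene
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O estradiol
CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12 testosterone
CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C cholesterol_core
CCC(=C(c1ccccc1)c1ccc(O)cc1)c1ccccc1 triaryl_ethylene
Oc1ccc(Cc2ccccc2)cc1-c1ccccc1 biphenyl_phenol
COc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1 methoxy_flavonoid
Oc1cccc2c1C(=O)c1c(O)cccc1C2=O dihydroxy_anthraquinone
CN(C)c1ccc(C(=C2C=CC(=[N+](C)C)C=C2)c2ccccc2)cc1 triarylmethane_dye
Clc1ccc(-c2nc3ccccc3s2)cc1 aryl_benzothiazole
CCCCCCCCc1ccc(-c2ccc(O)cc2O)cc1 alkyl_resorcinol
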