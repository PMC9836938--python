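# Codon reassignment schemes: monomer A decodes TCG, monomer B decodes TAG.
# pair_A / pair_B are the synthetase/tRNA pairs used for decoding (metadata).
# r.s. 1-3 encode two ncAAs (peptide macrocycles); r.s. 4-8 encode at least
# one alpha hydroxy acid (depsipeptide macrocycles, 1 or 2 ester bonds).
rs1:
  monomer_A: "1"   # AllocK
  monomer_B: "3"   # pIF
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: AfTyrRS(pIF)/AftRNATyr(A01)(CUA)
rs2:
  monomer_A: "1"   # AllocK
  monomer_B: "4"   # CbzK
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: 1R26PylRS(CbzK)/AlvtRNAdNPyl(8)(CUA)
rs3:
  monomer_A: "2"   # AlkynK
  monomer_B: "5"   # pAzF
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: AfTyrRS(pAzF)/AftRNATyr(A01)(CUA)
rs4:
  monomer_A: "7"   # AllocK-OH
  monomer_B: "3"   # pIF
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: AfTyrRS(pIF)/AftRNATyr(A01)(CUA)
rs5:
  monomer_A: "7"   # AllocK-OH
  monomer_B: "12"  # CbzK-OH
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: 1R26PylRS(CbzK)/AlvtRNAdNPyl(8)(CUA)
rs6:
  monomer_A: "8"   # AlkynK-OH
  monomer_B: "5"   # pAzF
  pair_A: MmPylRS/MmtRNAPyl(CGA)
  pair_B: AfTyrRS(pAzF)/AftRNATyr(A01)(CUA)
rs7:
  monomer_A: "14"  # F-OH
  monomer_B: "4"   # CbzK
  pair_A: MmPylRS(PheOH_6)/MmtRNAPyl(CGA)
  pair_B: 1R26PylRS/AlvtRNAdNPyl(8)(CUA)
rs8:
  monomer_A: "16"  # NapA-OH
  monomer_B: "1"   # AllocK
  pair_A: MmPylRS(ArOH)/MmtRNAPyl(CGA)
  pair_B: 1R26PylRS/AlvtRNAdNPyl(8)(CUA)
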