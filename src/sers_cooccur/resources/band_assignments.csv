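lo_cm1,hi_cm1,class_tag,label
420,447,lipid,cholesterol ring
460,470,protein,disulfide stretch
500,530,protein,disulfide stretch
548,558,protein,C-S / disulfide
566,574,protein,tryptophan
592,615,lipid,cholesterol
638,645,protein,tyrosine
646,650,protein,amino acid side chain
654,662,protein,C-S stretch
700,706,lipid,cholesterol
720,732,dna,adenine ring
748,758,protein,tryptophan
764,775,protein,tryptophan ring
775,783,lipid,lipid chain
805,830,dna,nucleic acid backbone
834,856,protein,tyrosine
865,875,protein,amino acid side chain
900,910,protein,amino acid side chain
1000,1010,protein,phenylalanine ring breathing
1018,1034,protein,phenylalanine
1050,1070,lipid,C-C stretch
1095,1108,lipid,C-C stretch
1110,1122,lipid,lipid intrachain C-C
1125,1142,protein,backbone C-C/C-N
1174,1186,dna,phosphate group
1215,1285,protein,amide III
1296,1306,lipid,CH2 twist
1310,1322,lipid,CH2 deformation
1340,1380,protein,tryptophan
1383,1395,lipid,CH3 deformation
1425,1448,lipid,CH2 scissoring
1455,1465,lipid,CH2/CH3 deformation
1495,1505,protein,amide II
1520,1595,protein,amide II
1600,1620,protein,aromatic ring / amide I
1640,1652,protein,amide I
1696,1712,protein,amide I
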