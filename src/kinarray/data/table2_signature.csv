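peptide_id,encoding_protein,flag_meljd_vs_mm200,flag_meljd_vs_p3post,flag_tissue
41_654_666,Erythrocyte membrane protein band 4.1,absent,significant_and_tissue,true
ANXA1_14_26,Annexin A1,significant_and_tissue,significant_and_tissue,true
ANXA2_17_29,Annexin A2 pseudogene 3; annexin A2; annexin A2 pseudogene 1,absent,significant,false
C1R_199_211,"Complement component 1, r subcomponent",absent,significant_and_tissue,true
CALM_93_105,Calmodulin 3; calmodulin 2; calmodulin 1,absent,absent,true
CD3Z_116_128,CD247 molecule,absent,significant,false
CD79A_181_193,"CD79a molecule, immunoglobulin-associated alpha",significant_and_tissue,significant_and_tissue,true
CDK2_8_20,Cyclin-dependent kinase 2,absent,absent,true
CDK7_157_169,Cyclin-dependent kinase 7,absent,significant,false
CRK_214_226,v-crk sarcoma virus CT10 oncogene homolog,significant,significant,false
CTNB1_79_91,"Catenin (cadherin-associated protein), beta",absent,significant,false
DCX_109_121,Doublecortin,absent,significant,false
DYR1A_312_324,Dual-specificity tyrosine-(Y)-phosphorylation regulated kinase 1A,significant_and_tissue,significant_and_tissue,true
EFS_246_258,Embryonal Fyn-associated substrate,absent,absent,true
EGFR_1062_1074,Epidermal growth factor receptor,absent,absent,true
EGFR_1103_1115,Epidermal growth factor receptor,significant,significant,false
EGFR_1165_1177,Epidermal growth factor receptor,absent,significant,false
EGFR_1190_1202,Epidermal growth factor receptor,significant,significant,false
EGFR_862_874,Epidermal growth factor receptor,significant_and_tissue,absent,true
ENOG_37_49,"Enolase 2 (gamma, neuronal)",absent,absent,true
EPHA1_774_786,EPH receptor A1,significant_and_tissue,significant_and_tissue,true
EPHA2_581_593,EPH receptor A2,absent,significant,false
EPHA2_765_777,EPH receptor A2,absent,absent,true
EPHA7_607_619,EPH receptor A7,absent,significant_and_tissue,true
EPHB1_771_783,EPH receptor B1,absent,significant_and_tissue,true
EPOR_361_373,Erythropoietin receptor,absent,absent,true
EPOR_419_431,Erythropoietin receptor,absent,significant,false
ERBB2_1241_1253,v-erb-b2 erythroblastic leukemia viral oncogene homolog 2,absent,absent,true
ERBB2_870_882,v-erb-b2 erythroblastic leukemia viral oncogene homolog 2,absent,absent,true
FAK1_569_581,PTK2 protein tyrosine kinase 2,significant,significant,false
FAK2_572_584,PTK2B protein tyrosine kinase 2 beta,significant,significant,false
FER_707_719,Fer (fps/fes related) tyrosine kinase,absent,significant_and_tissue,true
FES_706_718,Feline sarcoma oncogene,absent,absent,true
FGFR1_761_773,Fibroblast growth factor receptor 1,absent,absent,true
FGFR2_762_774,Fibroblast growth factor receptor 2,absent,absent,true
FGFR3_753_765,Fibroblast growth factor receptor 3,significant_and_tissue,significant_and_tissue,true
FRK_380_392,Fyn-related kinase,significant_and_tissue,significant_and_tissue,true
JAK1_1015_1027,Janus kinase 1,absent,significant_and_tissue,true
JAK2_563_577,Janus kinase 2,absent,significant,false
K2C6B_53_65,Keratin 6B,significant,significant,false
K2C8_425_437,Keratin 8 pseudogene 9,significant,significant,false
LAT_194_206,Linker for activation of T cells,significant,significant,false
LAT_249_261,Linker for activation of T cells,significant,significant,false
LCK_387_399,Lymphocyte-specific protein tyrosine kinase,significant_and_tissue,absent,true
MET_1227_1239,Met proto-oncogene (hepatocyte growth factor receptor),significant,significant,false
MK01_180_192,Mitogen-activated protein kinase 1,significant,significant,false
MK07_211_223,Mitogen-activated protein kinase 7,significant,significant,false
MK14_173_185,Mitogen-activated protein kinase 14,significant,significant,false
NPT2A_501_513,"Solute carrier family 34 (sodium phosphate), member 1",significant,significant,false
NTRK1_489_501,"Neurotrophic tyrosine kinase, receptor, type 1",absent,absent,true
NTRK2_696_708,"Neurotrophic tyrosine kinase, receptor, type 2",significant,significant,false
P85A_600_612,"Phosphoinositide-3-kinase, regulatory subunit 1 (alpha)",absent,significant_and_tissue,true
PAXI_111_123,Paxillin,absent,significant_and_tissue,true
PAXI_24_36,Paxillin,absent,absent,true
PDPK1_2_14,3-phosphoinositide dependent protein kinase-1,absent,absent,true
PDPK1_369_381,3-phosphoinositide dependent protein kinase-1,significant,significant,false
PECA1_706_718,Platelet/endothelial cell adhesion molecule,absent,absent,true
PGFRB_1002_1014,"Platelet-derived growth factor receptor, beta polypeptide",absent,significant,false
PGFRB_1014_1028,"Platelet-derived growth factor receptor, beta polypeptide",absent,significant_and_tissue,true
PGFRB_572_584,"Platelet-derived growth factor receptor, beta polypeptide",absent,absent,true
PGFRB_768_780,"Platelet-derived growth factor receptor, beta polypeptide",absent,significant,false
PGFRB_771_783,"Platelet-derived growth factor receptor, beta polypeptide",absent,significant,false
PLCG1_764_776,"Phospholipase C, gamma 1",absent,significant_and_tissue,true
PRRX2_202_214,Paired related homeoboX 2,significant,significant,false
RAF1_332_344,v-raf-1 murine leukemia viral oncogene homolog 1,significant,absent,false
RASA1_453_465,RAS p21 protein activator (GTPase activating protein) 1,absent,absent,true
RET_1022_1034,Ret proto-oncogene,absent,significant_and_tissue,true
RON_1346_1358,Macrophage stimulating 1 receptor (c-met-related tyrosine kinase),absent,significant,false
SRC8_CHICK_476_488,Cortactin,absent,significant_and_tissue,true
SRC8_CHICK_492_504,Cortactin,absent,significant_and_tissue,true
STAT1_694_706,Signal transducer and activator of transcription 1,absent,significant,false
STAT4_714_726,Signal transducer and activator of transcription 4,absent,significant,false
TEC_512_524,Tec protein tyrosine kinase,absent,significant,false
TYRO3_679_691,TYRO3 protein tyrosine kinase,significant,significant,false
VGFR1_1040_1052,Fms-related tyrosine kinase 1 (vascular endothelial growth factor),absent,significant,false
VGFR1_1049_1061,Fms-related tyrosine kinase 1 (vascular endothelial growth factor),significant,significant,false
VGFR1_1235_1247,Fms-related tyrosine kinase 1 (vascular endothelial growth factor),absent,significant_and_tissue,true
VGFR2_1046_1058,Kinase insert domain receptor (a type III receptor tyrosine kinase),significant,absent,false
VGFR2_1052_1064,Kinase insert domain receptor (a type III receptor tyrosine kinase),absent,significant,false
ZAP70_485_497,Zeta-chain (TCR) associated protein kinase,significant,significant,false
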