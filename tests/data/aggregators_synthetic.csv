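id,smiles
synagg_000,Oc1ccc(O)c(O)c1
synagg_001,COc1ccc(O)c(O)c1
synagg_002,Cc1ccc(O)c(O)c1
synagg_003,Oc1ccc(Cl)cc1O
synagg_004,Nc1ccc(O)c(O)c1
synagg_005,O=C(O)c1ccc(O)c(O)c1
synagg_006,CCc1ccc(O)c(O)c1
synagg_007,Oc1ccc(F)cc1O
synagg_008,Oc1ccc(Br)cc1O
synagg_009,Oc1cc(O)cc(O)c1
synagg_010,COc1cc(O)cc(O)c1
synagg_011,Cc1cc(O)cc(O)c1
synagg_012,Oc1cc(O)cc(Cl)c1
synagg_013,Nc1cc(O)cc(O)c1
synagg_014,O=C(O)c1cc(O)cc(O)c1
synagg_015,CCc1cc(O)cc(O)c1
synagg_016,Oc1cc(O)cc(F)c1
synagg_017,Oc1cc(O)cc(Br)c1
synagg_018,O=C1C=CC(=O)C(O)=C1
synagg_019,COC1=CC(=O)C=CC1=O
synagg_020,CC1=CC(=O)C=CC1=O
synagg_021,O=C1C=CC(=O)C(Cl)=C1
synagg_022,NC1=CC(=O)C=CC1=O
synagg_023,O=C1C=CC(=O)C(C(=O)O)=C1
synagg_024,CCC1=CC(=O)C=CC1=O
synagg_025,O=C1C=CC(=O)C(F)=C1
synagg_026,O=C1C=CC(=O)C(Br)=C1
synagg_027,Oc1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_028,COc1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_029,Cc1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_030,Oc1ccc(/C=C/c2ccc(Cl)cc2)cc1
synagg_031,Nc1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_032,O=C(O)c1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_033,CCc1ccc(/C=C/c2ccc(O)cc2)cc1
synagg_034,Oc1ccc(/C=C/c2ccc(F)cc2)cc1
synagg_035,Oc1ccc(/C=C/c2ccc(Br)cc2)cc1
synagg_036,O=C(/C=C/c1ccc(O)cc1)c1ccccc1
synagg_037,COc1ccc(/C=C/C(=O)c2ccccc2)cc1
synagg_038,Cc1ccc(/C=C/C(=O)c2ccccc2)cc1
synagg_039,O=C(/C=C/c1ccc(Cl)cc1)c1ccccc1
synagg_040,Nc1ccc(/C=C/C(=O)c2ccccc2)cc1
synagg_041,O=C(O)c1ccc(/C=C/C(=O)c2ccccc2)cc1
synagg_042,CCc1ccc(/C=C/C(=O)c2ccccc2)cc1
synagg_043,O=C(/C=C/c1ccc(F)cc1)c1ccccc1
synagg_044,O=C(/C=C/c1ccc(Br)cc1)c1ccccc1
synagg_045,O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)ccc12
synagg_046,COc1ccc(-c2oc3cc(O)ccc3c(=O)c2O)cc1
synagg_047,Cc1ccc(-c2oc3cc(O)ccc3c(=O)c2O)cc1
synagg_048,O=c1c(O)c(-c2ccc(Cl)cc2)oc2cc(O)ccc12
synagg_049,Nc1ccc(-c2oc3cc(O)ccc3c(=O)c2O)cc1
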