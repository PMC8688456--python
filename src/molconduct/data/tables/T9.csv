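table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T9,1,"2,2,3,3-Tetramethylbutane",CC(C)(C)C(C)(C)C,45.75,106.5,106.7,false,false
T9,2,"2,2,3-Trimethylpentane",CC(C)(C)C(C)CC,39.625,110,111.1,false,false
T9,3,"2,3,3-Trimethylpentane",CC(C)C(C)(C)CC,39.125,114.7,111.4,false,false
T9,4,"2,2,4-Trimethylpentane",CC(C)(C)CC(C)C,43.375,99.2,108.4,false,false
T9,5,"2,2-Dimethylhexane",CC(C)(C)CCCC,35.75,106.9,113.8,false,false
T9,6,"3,3-Dimethylhexane",CCC(C)(C)CCC,33.75,112,115.2,false,false
T9,7,3-Ethyl-3-methylpentane,CCC(C)(CC)CC,32.75,118.2,115.9,false,false
T9,8,"2,3,4-Trimethylpentane",CC(C)C(C)C(C)C,40.625,113.4,110.4,false,false
T9,9,"2,3-Dimethylhexane",CC(C)C(C)CCC,34.5,115.6,114.7,false,false
T9,10,3-Ethyl-2-methylpentane,CC(C)C(CC)CC,33.5,115.6,115.4,false,false
T9,11,"3,4-Dimethylhexane",CCC(C)C(C)CC,33.5,117.7,115.4,false,false
T9,12,"2,4-Dimethylhexane",CC(C)CC(C)CC,36,109.4,113,false,false
T9,13,"2,5-Dimethylhexane",CC(C)CCC(C)C,38.5,109,111.9,false,false
T9,14,2-Methylheptane,CC(C)CCCCC,30.375,117.6,117.6,false,false
T9,15,3-Methylheptane,CCC(C)CCCC,25.875,118,120.8,false,true
T9,16,4-Methylheptane,CCCC(C)CCC,28.375,117.7,119,false,false
T9,17,3-Ethylhexane,CCC(CC)CCC,27.875,118.5,119.4,false,false
T9,18,Octane,CCCCCCCC,22.75,125.7,123,false,false
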