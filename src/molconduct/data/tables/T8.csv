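table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T8,1,"2,2,3-Trimethylbutane",CC(C)(C)C(C)C,33.71,80.9,80.7,false,false
T8,2,3-Ethylpentane,CCC(CC)CC,23.14,93.5,92.1,false,false
T8,3,"3,3-Dimethylpentane",CCC(C)(C)CC,28,86.1,86.9,false,false
T8,4,"2,4-Dimethylpentane",CC(C)CC(C)C,30.86,80.6,83.8,false,false
T8,5,"2,3-Dimethylpentane",CC(C)C(C)CC,28.57,89.8,86.2,false,false
T8,6,"2,2-Dimethylpentane",CC(C)(C)CCC,29.14,79.2,85.6,false,false
T8,7,2-Methylhexane,CC(C)CCCC,24.86,90.1,90.3,false,false
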