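table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T1,1,"2,2-Dimethylpropane",CC(C)(C)C,17.6,9.5,,false,false
T1,2,"2,3-Dimethylbutane",CC(C)C(C)C,23.33,58.1,,false,false
T1,3,"2,2,3-Trimethylbutane",CC(C)(C)C(C)C,33.71,81,,false,false
T1,4,"2,2,3,3-Tetramethylbutane",CC(C)(C)C(C)(C)C,45.75,106.5,,false,false
T1,5,"2,3,3,4-Tetramethylpentane",CC(C)C(C)(C)C(C)C,52,141.5,,false,false
T1,6,"2,2,3,3,4-Pentamethylpentane",CC(C)C(C)(C)C(C)(C)C,66.3,161.1,,false,false
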