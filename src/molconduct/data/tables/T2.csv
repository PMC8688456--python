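table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T2,1,Hexane,CCCCCC,15,68.8,,false,false
T2,2,3-Methylpentane,CCC(C)CC,18.83,63.3,,false,false
T2,3,2-Methylpentane,CC(C)CCC,19.5,60.9,,false,false
T2,4,"2,2-Dimethylbutane",CC(C)(C)CC,23,49.8,,false,false
T2,5,"2,3-Dimethylbutane",CC(C)C(C)C,23.33,58.1,,false,false
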