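table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T7,1,2-Methylpentane,CC(C)CCC,19.5,60.9,59.8,false,false
T7,2,3-Methylpentane,CCC(C)CC,18.8,63.3,61.1,false,false
T7,3,"2,2-Dimethylbutane",CC(C)(C)CC,23,49.8,53.1,false,false
T7,4,"2,3-Dimethylbutane",CC(C)C(C)C,23.3,58.1,52.4,false,false
T7,5,Hexane,CCCCCC,15,68.8,68.5,false,false
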