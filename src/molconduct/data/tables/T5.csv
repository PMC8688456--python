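table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T5,1,"2,2-Dimethylpropane",CC(C)(C)C,17.6,9.5,,false,false
T5,2,"2,2-Dimethylbutane",CC(C)(C)CC,23,49.8,,false,false
T5,3,"2,2-Dimethylpentane",CC(C)(C)CCC,29.14286,79.2,,false,false
T5,4,"2,2-Dimethylhexane",CC(C)(C)CCCC,35.75,106.9,,false,false
T5,5,"2,2-Dimethylheptane",CC(C)(C)CCCCC,42.66667,131.9,,false,false
T5,6,"2,2-Dimethyloctane",CC(C)(C)CCCCCC,49.8,154,,false,false
T5,7,"2,2-Dimethylnonane",CC(C)(C)CCCCCCC,,,,true,false
T5,8,"2,2-Dimethyldecane",CC(C)(C)CCCCCCCC,64.5,200.1,,false,false
T5,9,"2,2-Dimethylundecane",CC(C)(C)CCCCCCCCC,72,220,,false,false
T5,10,"2,2-Dimethyldodecane",CC(C)(C)CCCCCCCCCC,,,,true,false
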