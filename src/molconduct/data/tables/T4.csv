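table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T4,1,2-Methylbutane,CC(C)CC,14.5,27.4,,false,true
T4,2,2-Methylpentane,CC(C)CCC,19.5,60.9,,false,false
T4,3,2-Methylhexane,CC(C)CCCC,24.85714,90.1,,false,false
T4,4,2-Methylheptane,CC(C)CCCCC,30.375,117.6,,false,false
T4,5,2-Methyloctane,CC(C)CCCCCC,36,143,,false,false
T4,6,2-Methylnonane,CC(C)CCCCCCC,41.7,166.9,,false,false
T4,7,2-Methyldecane,CC(C)CCCCCCCC,47.45455,189.3,,false,false
T4,8,2-Methylundecane,CC(C)CCCCCCCCC,53.25,208.9,,false,false
T4,9,2-Methyldodecane,CC(C)CCCCCCCCCC,59.07692,229.5,,false,false
T4,10,2-Methyltridecane,CC(C)CCCCCCCCCCC,64.92857,247.9,,false,false
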