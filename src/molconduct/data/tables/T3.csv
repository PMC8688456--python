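table_id,row_index,name,smiles,conduction_printed,bp_experimental,bp_predicted,missing_bp,erratum
T3,1,Butane,CCCC,7.5,0,,false,false
T3,2,Pentane,CCCCC,11.2,36.1,,false,false
T3,3,Hexane,CCCCCC,15,68.8,,false,false
T3,4,Heptane,CCCCCCC,18.85714,98.38,,false,false
T3,5,Octane,CCCCCCCC,22.75,125.6,,false,false
T3,6,Nonane,CCCCCCCCC,26.66667,150.7,,false,false
T3,7,Decane,CCCCCCCCCC,30.6,174.1,,false,false
T3,8,Undecane,CCCCCCCCCCC,34.54545,195,,false,false
T3,9,Dodecane,CCCCCCCCCCCC,38.5,216,,false,false
T3,10,Tridecane,CCCCCCCCCCCCC,42.46154,234,,false,false
T3,11,Tetradecane,CCCCCCCCCCCCCC,46.42857,255,,false,false
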