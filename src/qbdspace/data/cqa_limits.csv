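name,unit,lower,upper,basis
danshensu,mg/g Danshen,2.0,3.8,Danshen
hydroxysafflor_yellow_A,mg/g Honghua,5.1,7.6,Honghua
rosmarinic_acid,mg/g Danshen,1.8,2.2,Danshen
lithospermic_acid,mg/g Danshen,2.1,2.6,Danshen
salvianolic_acid_B,mg/g Danshen,36,45,Danshen
dry_matter,mg/g Material,400,550,Material
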