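study_label,tissue,half_life,sd,exposure_weight,type_weight,tissue_weight,duration_weight,divisor
lupton2014,Body,114.2,22.84,1,3,3,1,1.0
lupton2022,Steer Plasma,120.0,4.1,1,3,1,3,3.0
lupton2022,Heifer Plasma,106.0,23.1,1,3,1,3,3.0
lupton2022,Grouped Muscle,165.0,33.0,1,3,3,3,3.0
drew2022,Serum,74.1,13.4,3,1,1,3,2.0
drew2022,Muscle,77.0,15.4,3,1,3,3,2.0
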