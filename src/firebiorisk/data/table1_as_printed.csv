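unit_id,name,potential_area_km2,actual_area_km2,time_to_recover,total_species,endemic_species,specific_endemic_species
dhf_calcareous,Dense humid forest - calcareous substrates,2145,1720,0.5,225,108,23
dhf_ultramafic,Dense humid forest - ultramafic substrates,5891,1770,1,1360,1121,574
dhf_sed_volcanic,Dense humid forest - sedimentary and volcanic substrates,6709,3080,0.3,1367,1048,481
maquis_mid_low,Maquis - middle and low altitude,473,4223,0.5,1100,979,21
maquis_high,Maquis - high altitude,7,44,0.5,200,182,242
sclerophyll,Sclerophyll forest,1648,52,0.5,424,233,67
savanna,Savanna and secondary thickets,0,5311,0.01,410,45,4
TOTAL,TOTAL,,,,3260,2412,1437
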