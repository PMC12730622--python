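site_id,habitat_type,altitude_m,n_individuals,area_m2,aspect_label,aspect_deg,slope_deg,light_condition
1,Calcareous scree,1037,30,80,WNW,293,45,full-sun
2,Deciduous broad-leaved forest,652,5,25,NE,45,40,partial-shade
3,Deciduous broad-leaved forest,1150,70,110,N,0,30,partial-shade
4,Deciduous broad-leaved forest,1050,30,80,NNE,23,35,partial-shade
5,Deciduous broad-leaved forest,922,60,120,N,355,22,partial-shade
6,Deciduous broad-leaved forest,1057,50,96,NE,48,30,partial-shade
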