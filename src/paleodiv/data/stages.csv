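stage,series,max_ma,min_ma,is_international
Kasimovian,Pennsylvanian,307.0,303.7,1
Gzhelian,Pennsylvanian,303.7,298.9,1
Asselian,Cisuralian,298.9,293.5,1
Sakmarian,Cisuralian,293.5,290.1,1
Artinskian,Cisuralian,290.1,283.5,1
Kungurian,Cisuralian,283.5,273.0,1
Roadian,Guadalupian,273.0,266.9,1
Wordian,Guadalupian,266.9,264.3,1
Capitanian,Guadalupian,264.3,259.5,1
Wuchiapingian,Lopingian,259.5,254.1,1
Changhsingian,Lopingian,254.1,251.9,1
Induan,Lower Triassic,251.9,249.9,1
Olenekian,Lower Triassic,249.9,246.7,1
Anisian,Middle Triassic,246.7,241.5,1
Ladinian,Middle Triassic,241.5,237.0,1
Carnian,Upper Triassic,237.0,227.0,1
Norian,Upper Triassic,227.0,208.5,1
Rhaetian,Upper Triassic,208.5,201.4,1
Hettangian,Lower Jurassic,201.4,199.5,1
Sinemurian,Lower Jurassic,199.5,192.9,1
Pliensbachian,Lower Jurassic,192.9,184.2,1
Toarcian,Lower Jurassic,184.2,174.7,1
Aalenian,Middle Jurassic,174.7,170.9,1
Bajocian,Middle Jurassic,170.9,168.2,1
Bathonian,Middle Jurassic,168.2,165.3,1
Callovian,Middle Jurassic,165.3,161.5,1
Oxfordian,Upper Jurassic,161.5,154.8,1
Kimmeridgian,Upper Jurassic,154.8,149.2,1
Tithonian,Upper Jurassic,149.2,143.1,1
Berriasian,Lower Cretaceous,143.1,137.7,1
Valanginian,Lower Cretaceous,137.7,132.6,1
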