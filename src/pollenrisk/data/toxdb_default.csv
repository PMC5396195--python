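compound,pclass,contact_ld50_ug_per_bee,oral_ld50_ug_per_bee
Indoxacarb,insecticide,0.118,0.26
Cyfluthrin,insecticide,0.037,0.051
Thiamethoxam,insecticide,0.024,0.005
Abamectin,insecticide,0.03,
Carbaryl,insecticide,0.84,0.15
Acetamiprid,insecticide,7.9,14
Cyprodinil,fungicide,100,100
Iprodione,fungicide,400,25
Thiophanate-methyl,fungicide,100,100
Fluxapyroxad,fungicide,100,110.9
Difenoconazole,fungicide,101,177
Penthiopyrad,fungicide,312,385
Atrazine,herbicide,97,
Fenbuconazole,fungicide,290,
Trifloxystrobin,fungicide,200,200
Myclobutanil,fungicide,39.6,34
Fenpyroximate,insecticide,11,118.5
Thiacloprid,insecticide,37.83,17.32
Boscalid,fungicide,200,166
Phosmet,insecticide,0.62,0.37
Clothianidin,insecticide,0.044,0.004
Imidacloprid,insecticide,0.044,0.004
Spinetoram,insecticide,0.024,0.14
Spinosad,insecticide,0.003,0.057
Chlorantraniliprole,insecticide,4,104
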