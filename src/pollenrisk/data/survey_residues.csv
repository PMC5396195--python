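compound,mean_residue_ppb,n_detections,lod_ppb
Indoxacarb,557.1,2,35.5
Cyfluthrin,93.3,6,35.5
Thiamethoxam,21.5,5,3.6
Abamectin,21.9,1,3.6
Carbaryl,69.9,11,3.6
Acetamiprid,160.5,11,1.4
Cyprodinil,1216.4,24,0.4
Iprodione,929.3,4,355.3
Thiophanate-methyl,570,1,1.4
Fluxapyroxad,353.6,12,3.6
Difenoconazole,327.1,22,1.4
Penthiopyrad,119.2,8,1.4
Atrazine,28.2,6,35.5
Fenbuconazole,389.4,1,35.5
Trifloxystrobin,14.1,18,0.4
Myclobutanil,49.5,1,35.5
Fenpyroximate,3.5,1,1.4
Thiacloprid,9.6,3,3.6
Boscalid,0,0,35.5
Phosmet,0,0,355.3
Clothianidin,0,0,35.5
Imidacloprid,0,0,3.6
Spinetoram,0,0,1.4
Spinosad,0,0,1.4
Chlorantraniliprole,0,0,3.6
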