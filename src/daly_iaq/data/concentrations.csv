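pollutant,concentration_ug_m3
"1,1,2,2-Tetrachloroethane",0.42
"1,1,2-Trichloroethane",0.46
"1,1-Dichloroethene",1.2
"1,2-Dibromoethane",0.14
"1,2-Dichloroethane",0.34
"1,3-Butadiene",0.46
"1,4-Dichlorobenzene",50
2-Butoxyethanol,2.6
2-Ethylhexanol,3.7
2-Ethoxyethanol,0.43
2-Methoxyethanol,0.12
Acetaldehyde,22
Acrolein,2.3
Acrylonitrile,0.27
Ammonia,28
Arsenic,9.8e-4
Atrazine,5.9e-4
Benzaldehyde,2.5
Benzene,2.5
Benzo[a]pyrene,9.1e-5
Benzyl chloride,0.5
Beryllium,1.6e-6
Bis(2-ethylhexyl) phthalate,0.14
Bromodichloromethane,0.49
Bromoform,0.39
Cadmium,2.6e-3
Carbon disulfide,0.34
CO,810
Carbon tetrachloride,0.68
Chlorobenzene,0.68
Chloroethane,0.26
Chloroform,1.5
Chloromethane,1.8
Chromium,2.2e-3
Crotonaldehyde,4.7
Cyclohexane,5.2
Di(2-ethylhexyl) adipate,1.6e-2
"Dibenzo[a,c+a,h]anthracene",1.4e-5
Dibromochloromethane,0.44
d-Limonine,23
Ethanol,860
Ethylbenzene,3.9
Formaldehyde,69
Hexachlorobutadiene,1.7
Hexane,7.3
Isopropylbenzene,0.4
Manganese,3.3e-3
Methyl ethyl ketone,7.4
Mercury,1.6e-4
Methyl methacrylate,0.27
Methylene chloride,8.2
Methyl isobutyl ketone,1.2
Methyl tert-butyl ether,12
Naphthalene,1.2
NO2,13.1
o-Phenylphenol,0.13
Ozone,17.2
Pentachlorophenol,2.9e-3
PM2.5,15.9
Styrene,5.9
SO2,2.9
Tetrachloroethene,1.7
Tetrahydrofuran,15
Toluene,2.3
Trichloroethene,0.16
Vinyl chloride,1.7
"Xylene, o",8.2
"Xylene, m/p",9.7
Xylenes,7.4
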