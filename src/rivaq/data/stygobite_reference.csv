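order,species,kp_ranges
Mesogastropoda,Islamia moquiniana,3-6;97-103
Ostracoda,Fabaeformiscandona wegelini,97-103
Bathynellacea,Parabathynella cf. stygia,96-97
Amphipoda,Crangonyx subterraneus,96-97
Amphipoda,Niphargopsis casparyi,4-5;96-103;109-110
Amphipoda,Niphargus fontanus,4-5;96-98;109-110
Amphipoda,Niphargus kochianus,4-6;97
Amphipoda,Niphargus rhenorhodanensis,96-103;109-110
Amphipoda,Salentinella juberthiae,96-97;109-110
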