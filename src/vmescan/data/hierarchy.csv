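child,parent
Cerianthidae,Ceriantharia
Holaxonia,Alcyonacea
Calaxonia,Alcyonacea
Scleraxonia,Alcyonacea
Primnoidae,Alcyonacea
Isididae,Alcyonacea
Solenosmilia,Scleractinia
Lophelia,Scleractinia
Desmophyllum,Scleractinia
Madrepora,Scleractinia
Goniocorella,Scleractinia
Enallopsammia,Scleractinia
Oculina,Scleractinia
Anthoathecata,Hydroidolina
Leptothecata,Hydroidolina
Demospongiae,Porifera
Hexactinellida,Porifera
Calcarea,Porifera
Homoscleromorpha,Porifera
Hexasterophora,Hexactinellida
Amphidiscophora,Hexactinellida
Cidaroida,Echinoidea
Euryalida,Ophiuroidea
Serpulidae,Polychaeta
Bathylasmatidae,Arthropoda
Eucratea loricata,Bryozoa
Cheilostomatida,Bryozoa
Ctenostomatida,Bryozoa
Gymnolaemata,Bryozoa
Stenolaemata,Bryozoa
Syringammina,Xenophyophoroidea
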