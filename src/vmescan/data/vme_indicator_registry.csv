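taxon,rank,group,parent,NPFC,SPRFMO,NEAFC,NAFO_ABNJ,CCAMLR,SEAFO,GFCM,SIOFA
Actiniaria,order,Cnidaria,,no,yes,no,no,yes,no,no,yes
Ceriantharia,subclass,Cnidaria,,no,no,qualified:Cerianthidae,qualified:Cerianthidae,no,qualified:Cerianthidae,yes,no
Alcyonacea,order,Cnidaria,,yes,yes,yes,qualified:Holaxonia;Calaxonia;Scleraxonia,yes,yes,yes,yes
Pennatulacea,order,Cnidaria,,no,yes,yes,yes,yes,yes,yes,yes
Antipatharia,order,Cnidaria,,yes,yes,qualified:Schizopathidae;Leiopathidae;Antipathidae,yes,yes,yes,yes,yes
Scleractinia,order,Cnidaria,,yes,qualified:Solenosmilia;Goniocorella;Oculina;Enallopsammia;Madrepora;Lophelia,yes,qualified:Enallopsammia rostrata;Lophelia pertusa;Madrepora oculata;Solenosmilia variabilis,yes,yes,yes,yes
Hydroidolina,subclass,Cnidaria,,no,qualified:Anthoathecata;Leptothecata,no,no,yes,qualified:Anthoathecata,yes,qualified:Anthoathecata
Stylasteridae,family,Cnidaria,Hydroidolina,no,yes,yes,no,yes,no,qualified:note=as subclass Hydroidolina,yes
Zoantharia,order,Cnidaria,,no,yes,no,no,yes,yes,no,yes
Brisingida,order,Echinodermata,,no,yes,no,no,no,no,no,no
Crinoida,class,Echinodermata,,no,yes,qualified:note=stalked only,qualified:note=stalked only,qualified:note=stalked only,yes,yes,qualified:note=stalked only
Echinoidea,class,Echinodermata,,no,no,no,no,qualified:Cidaroida,no,no,qualified:Cidaroida
Ophiuroidea,class,Echinodermata,,no,no,no,no,qualified:Euryalida,qualified:note=basket stars,no,qualified:Euryalida
Arthropoda,phylum,OtherTaxa,,no,no,qualified:note=chemosynthetic ecosystem decapods only,no,qualified:Bathylasmatidae,no,no,qualified:Bathylasmatidae
Ascidiacea,class,OtherTaxa,,no,no,no,yes,yes,yes,no,yes
Bivalvia,class,OtherTaxa,,no,no,qualified:note=chemosynthetic communities,no,qualified:Adamussium colbecki,no,qualified:note=chemosynthetic communities & Gryphaeidae,no
Brachiopoda,phylum,OtherTaxa,,no,no,no,no,yes,no,no,yes
Bryozoa,phylum,OtherTaxa,,no,qualified:Cheilostomatida;Ctenostomatida,qualified:Eucratea loricata,qualified:note=fenestrate taxa,yes,yes,qualified:Gymnolaemata;Stenolaemata,yes
Polychaeta,class,OtherTaxa,,no,no,qualified:note=chemosynthetic communities,no,qualified:Serpulidae,qualified:Serpulidae,qualified:note=chemosynthetic communities and Canalipalpata,qualified:Serpulidae
Porifera,phylum,OtherTaxa,,no,qualified:Demospongiae;Hexactinellida,yes,yes,qualified:Demospongiae;Hexactinellida,yes,qualified:Demospongiae;Amphidiscophora;Hexasterophora,qualified:Demospongiae;Hexactinellida
Pterobranchia,class,OtherTaxa,,no,no,no,no,yes,no,no,yes
Xenophyophoroidea,suborder,OtherTaxa,,no,no,yes,yes,yes,no,no,yes
Chemosynthetic taxa,,Feature,,no,no,qualified:note=0-2000 m,no,yes,no,yes,yes
Seamounts as a whole,,Feature,,no,no,qualified:note=VME element,yes,no,no,qualified:note=VME-indicator feature,no
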