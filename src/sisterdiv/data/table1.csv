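pair_id,galler_name,n_galler,galler_hosts,host_age_galler,erm_p_galler_printed,nongaller_name,n_nongaller,nongaller_hosts,host_age_nongaller,erm_p_nongaller_printed
Euurina,Euurina,400,"Salix, Populus",58,0.059,Nematus melanaspis-group,25,"Salicaceae, Betulaceae",94,0.94
Bacconematus,Bacconematus,1,Ribes,35,1.00,Eitelius,2,Salix,35,0.50
Pristolina,Pristolina,4,Vaccinium,0,0.50,Pristicampus,3,Potentilla,0,0.67
Micronematus,Micronematus,1,Prunus,70*,0.97,Pristiphora subgenus Sala,30,"Fagaceae, Betulaceae, Salicaceae, Fabaceae, Rosaceae, Grossulariaceae, Malvaceae",114,0.033
Kladothrips,Kladothrips,24,Acacia,0,0.21,Rhopalothripoides,6,Acacia,0,0.83
Cynipidae+Synergini,gall-inducing Cynipidae + Synergini,1369,"Fagaceae, Rosaceae, Papaveraceae, Lamiaceae, Asteraceae, Anacardiaceae, Smilacaceae, Valerianaceae, Apiaceae, Sapindaceae",144,0.24,"Figitidae (in part): Charpinae, Anacharitinae, Figitinae, Aspicerinae",435,"Diptera, Neuroptera, Hymenoptera",300,0.76
Agaonidae+Otitesellinae,Agaonidae + Otitesellinae,690,Ficus,60,0.15,Sycoryctinae,121,Agaonidae + Sycoryctinae,60,0.85
Eurostina,Eurostina,41,"Asteraceae (Solidago, Chrysothamnus, Gutierrezia)",0,0.54,Euaresta,46,"Asteraceae (Ambrosia, Xanthium, Dicoria)",0,0.48
Oedapidina,Oedapidina,88,Asteraceae,42,0.71,Tephrellini,210,"Acanthaceae, Lamiaceae, Verbenaceae",45,0.30
Hexomyza,Hexomyza,16,Liliopsida/Eudicotyledons,144,0.95,Ophiomyia + Tropicomyia,282,Liliopsida/Eudicotyledons,144,0.054
Apiomorpha,Apiomorpha,150,Eucalyptus,65,0.020,Ourococcus,3,"Myrtaceae, Casuarinaceae",104,0.99
Maskellia,Maskellia,2,Eucalyptus,65,1.00,Aspidiotini; Pseudaonidina; Odonaspidini; non-pupillarial Parlatorini,874,Magnoliphyta/Coniferophyta,366,0.0023
Cerataphidini,Cerataphidini,73,Styrax,0,0.053,Thelaxes (Thelaxinae),4,Quercus,0,0.96
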