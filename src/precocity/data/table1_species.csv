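species,family,s50,sex_expression,leaf_habit,fruit_type,dbh95_cm,n_obs
Magnolia_obovata,Magnoliaceae,0.358,cosexual,deciduous,fleshy,56.1,41
Magnolia_salicifolia,Magnoliaceae,0.377,cosexual,deciduous,fleshy,30.3,66
Neolitsea_aciculata,Lauraceae,0.244,dioecious,evergreen,fleshy,23.4,131
Neolitsea_sericea,Lauraceae,0.113,dioecious,evergreen,fleshy,26.0,58
Litsea_coreana,Lauraceae,0.284,dioecious,evergreen,fleshy,71.0,21
Machilus_japonica,Lauraceae,0.372,cosexual,evergreen,fleshy,38.1,45
Cinnamomum_yabunikkei,Lauraceae,0.081,cosexual,evergreen,fleshy,30.7,47
Symplocos_prunifolia,Symplocaceae,0.668,cosexual,evergreen,fleshy,20.3,34
Styrax_japonica,Styracaceae,0.186,cosexual,deciduous,dry,25.3,58
Pieris_japonica,Ericaceae,0.537,cosexual,evergreen,dry,16.3,73
Lyonia_ovalifolia,Ericaceae,0.397,cosexual,deciduous,dry,10.3,73
Clethra_barbinervis,Clethraceae,0.393,cosexual,deciduous,dry,18.2,71
Camellia_japonica,Theaceae,0.214,cosexual,evergreen,dry,33.1,40
Eurya_japonica,Pentaphylacaceae,0.210,dioecious,evergreen,fleshy,7.9,76
Gamblea_innovans,Araliaceae,0.216,dioecious,deciduous,fleshy,30.3,52
Chengiopanax_sciadophylloides,Araliaceae,0.280,cosexual,deciduous,fleshy,29.6,58
Aralia_elata,Araliaceae,0.150,cosexual,deciduous,fleshy,16.2,38
Ilex_pedunculosa,Aquifoliaceae,0.140,dioecious,evergreen,fleshy,28.3,81
Osmanthus_heterophyllus,Oleaceae,0.101,dioecious,evergreen,fleshy,23.7,82
Ligustrum_japonicum,Oleaceae,0.277,cosexual,evergreen,fleshy,12.8,31
Cornus_macrophylla,Cornaceae,0.388,cosexual,deciduous,fleshy,40.4,47
Castanopsis_cuspidata,Fagaceae,0.358,cosexual,evergreen,dry,54.2,40
Photinia_glabra,Rosaceae,0.220,cosexual,evergreen,fleshy,40.7,40
Laurocerasus_spinulosa,Rosaceae,0.284,cosexual,evergreen,fleshy,57.6,22
Mallotus_japonicus,Euphorbiaceae,0.062,dioecious,deciduous,dry,34.8,91
Zanthoxylum_piperitum,Rutaceae,0.136,dioecious,deciduous,dry,6.4,41
Zanthoxylum_ailanthoides,Rutaceae,0.221,dioecious,deciduous,dry,46.9,70
Acer_palmatum,Sapindaceae,0.327,cosexual,deciduous,dry,38.4,57
Acer_rufinerve,Sapindaceae,0.087,dioecious,deciduous,dry,35.3,155
Illicium_anisatum,Schisandraceae,0.422,cosexual,evergreen,dry,16.6,50
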