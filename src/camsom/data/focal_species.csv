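code,scientific_name,english_name,taxon,game,mass_kg,recorded
Tapi.te,Tapirus terrestris,Lowland tapir,mammal,1,160,1
Pant.on,Panthera onca,Jaguar,mammal,1,80,0
Puma.co,Puma concolor,Puma,mammal,1,45,0
Taya.pe,Tayassu pecari,White lipped peccary,mammal,1,32,0
Maza.am,Mazama americana,Red brocket deer,mammal,1,30,1
Prio.ma,Priodontes maximus,Giant armadillo,mammal,1,30,0
Dico.ta,Dicotyles tajacu,Collared peccary,mammal,1,25,1
Maza.ne,Mazama nemorivaga,Gray brocket deer,mammal,1,18,1
Leop.pa,Leopardus pardalis,Ocelot,mammal,1,15,1
Cuni.pa,Cuniculus paca,Paca,mammal,1,9.5,1
Puma.ja,Puma yagouaroundi,Jaguarundi,mammal,1,8,0
Leop.wi,Leopardus wiedii,Margay,mammal,1,6,1
Nasu.na,Nasua nasua,South American coati,mammal,1,5.1,1
Dasy.fu,Dasyprocta fuliginosa,Agouti,mammal,1,4.5,1
Dasypus,Nonspecific small Cingulata,Armadillos,mammal,1,6,1
Hadro.sp,Hadrosciurus spadiceus,Southern Amazon red squirrel,mammal,1,1.2,1
Myrm.tr,Myrmecophaga tridactyla,Giant anteater,mammal,0,30.5,1
Atel.mi,Atelocynus microtis,Short-eared dog,mammal,0,7.75,1
Speo.ve,Speothos venaticus,Bush dog,mammal,0,6,0
Proc.ca,Procyon cancrivorus,Crab-eating raccoon,mammal,0,5.4,0
Eira.ba,Eira barbara,Tayra,mammal,0,4.85,1
Tama.te,Tamandua tetradactyla,Southern tamandua,mammal,0,4.5,1
Dide.ma,Didelphis marsupialis,Common opossum,mammal,0,1.09,1
Myop.pr,Myoprocta pratti,Acouchi,mammal,0,0.75,1
Mitu.tu,Mitu tuberosum,Curassow,bird,1,3,0
Pene.ja,Penelope jacquacu,Spix's guan,bird,1,1.2,1
Psop.le,Psophia leucoptera,Trumpeters,bird,1,1.28,1
Tina.sp,Tinamus spp.,Large tinamou,bird,1,1.2,1
Cryp.sp,Crypturellus spp.,Small tinamou,bird,1,0.42,1
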