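# Published species-mean morphometrics and dissection-calculated bite forces for
# 19 parrot species (Psittaciformes; families Cacatuidae, Psittaculidae,
# Psittacidae). Body masses are literature species means; skull mass, skull
# length and one-side total jaw muscle mass are dissection means; bite force is
# the PCSA-lever model output. SE columns are blank where fewer than three
# individuals were available or where no SE was published.
species,family,n_individuals,body_mass_g,skull_mass_g,skull_mass_se_g,skull_length_mm,skull_length_se_mm,jaw_muscle_mass_g,jaw_muscle_mass_se_g,bite_force_n,bite_force_se_n,bf_bm_ratio
Cacatua_alba,Cacatuidae,3,570.0,12.6,1.4,78.0,2.2,4.8,0.7,180.4,,0.316
Cacatua_galerita,Cacatuidae,3,720.4,12.0,,76.9,,6.8,,167.3,24.2,0.232
Cacatua_moluccensis,Cacatuidae,1,835.0,18.7,,91.3,,6.6,,264.7,,0.317
Melopsittacus_undulatus,Psittaculidae,1,29.0,0.4,,27.3,,0.1,,12.4,,0.428
Psittacula_eupatria,Psittaculidae,1,214.0,5.0,,59.0,,2.7,,105.7,,0.480
Psittacula_krameri,Psittaculidae,4,116.1,2.0,0.0,45.8,0.9,0.7,0.1,34.6,,0.298
Ara_ararauna,Psittacidae,3,1125.0,20.4,1.0,106.4,5.3,7.1,0.7,201.1,57.6,0.179
Ara_chloropterus,Psittacidae,3,1214.0,35.6,3.6,117.8,1.5,11.8,1.2,374.9,46.6,0.309
Ara_macao,Psittacidae,1,1015.0,31.5,,103.9,,6.5,,443.8,,0.437
Amazona_aestiva,Psittacidae,2,451.0,6.4,,65.6,,1.8,,117.7,,0.261
Amazona_amazonica,Psittacidae,3,370.0,6.6,1.0,67.6,2.0,1.8,0.1,83.1,8.1,0.225
Amazona_auropalliata,Psittacidae,1,476.9,6.5,,65.6,,2.4,,93.6,,0.196
Amazona_autumnalis,Psittacidae,2,416.0,5.7,,72.2,,2.0,,84.9,,0.204
Amazona_farinosa,Psittacidae,1,626.0,9.7,,79.8,,3.3,,136.1,,0.217
Amazona_oratrix,Psittacidae,1,517.0,9.6,,72.4,,1.5,,123.0,,0.238
Amazona_ochrocephala,Psittacidae,3,476.9,5.5,0.3,65.3,2.2,2.1,0.2,77.3,7.1,0.162
Myiopsitta_monachus,Psittacidae,3,120.0,1.3,0.2,41.8,2.8,0.5,0.0,21.3,2.4,0.178
Poicephalus_senegalus,Psittacidae,2,147.0,2.7,,49.6,,1.0,,34.8,,0.237
Psittacus_erithacus,Psittacidae,5,333.0,6.8,0.5,71.5,1.8,2.7,0.4,84.1,6.2,0.252
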