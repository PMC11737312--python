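# Published transducer-measured bite forces for nine parrot species, together
# with bite forces predicted from the mandibular adductor-scar power law
# (BF = 0.94 * scar_length^2.195) applied to skulls of the same species.
# Predicted values are blank where no skull image was available. Ratios are
# bite force divided by body mass (N/g) as printed.
species,n_individuals,body_mass_g,body_mass_se_g,measured_bite_force_n,measured_bf_bm_ratio,predicted_bite_force_n,predicted_bf_bm_ratio
Anodorhynchus_hyacinthinus,7,1253.7,34.5,538.86,0.4298,466.81,0.3723
Ara_ararauna,13,1040.2,20.4,259.77,0.2497,209.78,0.2017
Ara_chloropterus,9,1140.8,28.9,350.22,0.307,393.44,0.3449
Ara_glaucogularis,1,866,,290,0.3349,,
Ara_macao,5,1000.6,71.4,224.8,0.2247,286.74,0.2866
Ara_militaris,5,809.8,71.2,237.7,0.2935,222.77,0.2751
Ara_severus,1,400,,59,0.1475,,
Aratinga_canicularis,1,85,,53.6,0.6306,38.78,0.4562
Trichoglossus_haematodus,6,120,,52.45,0.4371,23.97,0.1998
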