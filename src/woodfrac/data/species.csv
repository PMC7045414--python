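species_name,abbreviation,family,soil_class
Eucalyptus piperita,Euc_pip,Myrtaceae,low
Angophora costata,Ang_cos,Myrtaceae,low
Banksia serrata,Ban_ser,Proteaceae,low
Eucalyptus haemastoma,Euc_hae,Myrtaceae,low
Banksia ericifolia,Ban_eri,Proteaceae,low
Leptospermum poligalifolium,Lep_pol,Myrtaceae,low
Syncarpia glomulifera,Syn_glo,Myrtaceae,low
Persoonia linearis,Per_lin,Proteaceae,low
Callicoma serratifolia,Cal_ser,Cunoniaceae,high
Ceratopetalum apetalum,Cer_ape,Cunoniaceae,high
Pittosporum undulatum,Pit_und,Pittosporaceae,high
Syzygium oleosum,Syz_ole,Myrtaceae,high
Synoum glandulosum,Syn_gla,Meliaceae,high
Trochocarpa laurina,Tro_lau,Ericaceae,high
Cryptocarya macrocarpa,Cry_mac,Lauraceae,high
Sloanea australis,Slo_aus,Elaeocarpaceae,high
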