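(cartilaginous_fish:430,((basal_rayfinned_fish:400,teleost_fish:400)Actinopterygii:30,(coelacanth:415,(amphibians:352,(reptiles:318,mammals:318)Amniota:34)Tetrapoda:63)Sarcopterygii:15)Osteichthyes:35)Gnathostomata;
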