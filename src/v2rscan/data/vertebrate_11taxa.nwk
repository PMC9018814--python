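((elephant_shark:420,(bamboo_shark:265,smalltooth_sawfish:265)Elasmobranchii:155)Chondrichthyes:45,((reedfish:400,(sterlet:360,(spotted_gar:320,zebrafish:320)Neopterygii:40)Actinopteri:40)Actinopterygii:30,(coelacanth:415,((caecilian:300,western_clawed_frog:300)Amphibia:52,mouse:352)Tetrapoda:63)Sarcopterygii:15)Osteichthyes:35)Gnathostomata;
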