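lineage	V2R2	ancV2R	fV2R	tV2R
cartilaginous_fish	P	P	P	A
basal_rayfinned_fish	P	P	P	P
teleost_fish	P	A	P	A
coelacanth	P	A	P	P
amphibians	P	P	P	P
reptiles	P	A	A	P
mammals	P	A	A	P
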