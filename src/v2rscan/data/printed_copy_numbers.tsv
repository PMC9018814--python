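species	common_name	assembly	V2R2	ancV2R	tV2R	fV2R	fig2b
Callorhinchus_milii	elephant_shark	Callorhinchus_milii-6.1.3	1	1	0	26	1
Hydrolagus_affinis	rabbitfish	UP_Haf1	1	1	0	39	0
Scyliorhinus_torazame	cloudy_catshark	Storazame_v1.0	1	1	0	21	0
Carcharodon_carcharias	white_shark	ASM360424v1	1	1	0	12	0
Rhincodon_typus	whale_shark	ASM164234v2	1	0	0	21	0
Chiloscyllium_punctatum	bamboo_shark	Cpunctatum_v2.1	1	1	0	24	1
Leucoraja_erinacea	little_skate	LER_WGS_1	1	1	0	6	0
Amblyraja_radiata	thorny_skate	sAmbRad1.pri	1	1	0	6	0
Pristis_pectinata	smalltooth_sawfish	sPriPec2.pri	1	1	0	22	1
Erpetoichthys_calabaricus	reedfish	fErpCal1.1	1	1	3	183	1
Acipenser_ruthenus	sterlet	ASM1064508v1	1	1	3	41	1
Lepisosteus_oculatus	spotted_gar	LepOcu1	1	1	0	47	1
Anguilla_japonica	japanese_eel	Ajp_01	1	0	0	63	0
Danio_rerio	zebrafish	GRCz11	1	0	0	71	1
Latimeria_chalumnae	coelacanth	LatCha1	1	0	75	13	1
Xenopus_tropicalis	western_clawed_frog	UCB_Xtro_10.0	1	1	689	0	1
Geotrypetes_seraphini	caecilian	aGeoSer1.1	1	0	273	1	1
Anolis_carolinensis	anole_lizard	AnoCar2.0	1	0	63	0	0
Mus_musculus	mouse	GRCm38.p6	7	0	147	0	1
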