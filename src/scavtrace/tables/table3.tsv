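primer_pair	sample_id	sample_type	species_assignment	raw_blast_species	carrion_flag
COI_BirdF1_AWCintR2	P-165A	feces	Lophura leucomelanos	Lophura nycthemera	0
COI_BirdF1_AWCintR2	R-12-619	stomach	Zosterops japonicus	Zosterops japonicus	1
COI_BirdF1_AWCintR2	R-12-620	stomach	Zosterops japonicus	Zosterops japonicus	0
COI_BirdF1_AWCintR2	R-12-623	stomach	Myadestes obscurus	Myadestes obscurus	0
COI_BirdF1_AWCintR2	R-12-624	stomach	Zosterops japonicus	Zosterops japonicus	0
COI_BirdF1_AWCintR2	R-12-626	stomach	Lophura leucomelanos	Lophura nycthemera	0
COI_BirdF1_AWCintR2	R-12-627	stomach	Zosterops japonicus	Zosterops japonicus	0
COI_BirdF1_AWCintR2	R-12-631	stomach	Zosterops japonicus	Zosterops japonicus	0
COI_BirdF1_AWCintR2	R-12-637	stomach	Zosterops japonicus	Zosterops japonicus	1
COI_BirdF1_AWCintR2	R-12-640	stomach	Zosterops japonicus	Zosterops japonicus	0
COI_BirdF1_AWCintR2	R-12-642	stomach	Zosterops japonicus	Zosterops japonicus	1
COI_BirdF1_AWCintR2	R-12-661	stomach	Zosterops japonicus	Zosterops japonicus	1
COI_BirdF1_AWCintR2	R-12-662	stomach	Zosterops japonicus	Zosterops japonicus	1
COI_BirdF1_AWCintR2	R-12-665	stomach	Zosterops japonicus	Zosterops japonicus	1
Cytb_CorL_Cor3	P-002A	feces	Meleagris gallopavo	Meleagris gallopavo	1
Cytb_CorL_Cor3	P-003A	feces	Meleagris gallopavo	Meleagris gallopavo	0
Cytb_CorL_Cor3	P-018A	feces	Myadestes obscurus	Myadestes obscurus	1
Cytb_CorL_Cor3	P-023A	feces	Myadestes obscurus	Myadestes obscurus	1
Cytb_CorL_Cor3	P-025A	feces	Myadestes obscurus	Myadestes obscurus	0
Cytb_CorL_Cor3	P-166A	feces	Myadestes obscurus	Myadestes obscurus	0
Cytb_CorL_Cor3	R-12-619	stomach	Zosterops japonicus	Zosterops japonicus	1
Cytb_CorL_Cor3	R-12-623	stomach	Myadestes obscurus	Myadestes obscurus	0
Cytb_CorL_Cor3	R-12-626	stomach	Lophura leucomelanos	Lophura nycthemera	0
Cytb_CorL_Cor3	R-12-627	stomach	Zosterops japonicus	Zosterops japonicus	0
Cytb_CorL_Cor3	R-12-631	stomach	Zosterops japonicus	Zosterops japonicus	0
Cytb_CorL_Cor3	R-12-637	stomach	Zosterops japonicus	Zosterops japonicus	1
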