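# Karyotype records for Pedipalpi, Ricinulei and Solifugae (new plus literature data).
# composition uses the compact pair-list grammar and includes the sex pair when one was
# listed; morphology_note holds qualitative calls when no pair list was printed.
# nor_loci: semicolon-separated location tokens, one per locus
# (NORt/NORpt/NORqt terminal; NORsubt/NORpsubt/NORqsubt subterminal; NORi/NORqi
# interstitial; NORperic pericentric; NORarm whole-arm).
key	taxon	order	source	two_n	two_n_max	sex_scored	composition	morphology_note	sex_system	nor_count	nor_loci	telomere	ch_pattern	first_pair_prominent	x_linked_nor
Charinus_cavernicolus	Charinus cavernicolus	Amblypygi	literature	76		male	5m+9sm+18st+6a								
Charinus_dominicanus	Charinus dominicanus	Amblypygi	literature	42		male	16m+5sm								
Charinus_neocaledonicus	Charinus neocaledonicus	Amblypygi	literature	74		male	9m+2sm+2st+24a			1	NORt				0
Charinus_pescotti	Charinus pescotti	Amblypygi	literature	74		male	9m+5sm+23a			1	NORt				0
Charon_cf_grayi	Charon cf. grayi	Amblypygi	this_study	70		both	4m+3sm+27mono+1a		XY_heteromorphic	2	NORpt;NORpt				1
Sarax_aff_batuensis	Sarax aff. batuensis	Amblypygi	literature	56		male	5m+8sm+6st+9a								
Sarax_huberi	Sarax huberi	Amblypygi	literature	50		male	15m+2st+8a								
Sarax_ioanniticus	Sarax ioanniticus	Amblypygi	literature	72		female		monop_predominant							
Sarax_seychellarum	Sarax seychellarum	Amblypygi	literature	22		both	9m+2sm			1	NORi	TTAGG			0
Sarax_brachydactylus	Sarax sp. (brachydactylus group)	Amblypygi	literature	74		male	9m+3sm+2st+23a								
Damon_medius	Damon medius	Amblypygi	this_study+literature	70		male		bip_and_monop		2	NORpt;NORpt	TTAGG			0
Euphrynichus_amanica	Euphrynichus amanica	Amblypygi	this_study	78		male	15m+4sm+20mono			3	NORt;NORpt;NORpt				0
Euphrynichus_bacillifer	Euphrynichus bacillifer	Amblypygi	this_study	56		male	22m+2sm+1st+3a			1	NORperic				0
Phrynichus_ceylonicus	Phrynichus ceylonicus	Amblypygi	this_study	52		both	17m+3m/sm+5sm+1st			3	NORt;NORt;NORt				0
Acanthophrynus_coronatus	Acanthophrynus coronatus	Amblypygi	this_study	86		male	27bi+6st+10a			1	NORpt	TTAGG			0
Heterophrynus_cf_elaphus	Heterophrynus cf. elaphus	Amblypygi	this_study	76		male	17bi+21mono			1	NORqt				0
Heterophrynus_longicornis	Heterophrynus longicornis	Amblypygi	literature	66		both	24m+3sm+6st			2	NORt;NORt				0
Paraphrynus_aztecus	Paraphrynus aztecus	Amblypygi	literature	36		male	14m+4sm								
Paraphrynus_carolynae	Paraphrynus carolynae	Amblypygi	literature	30		male	12m+3sm								
Paraphrynus_cubensis	Paraphrynus cubensis	Amblypygi	literature	34		male	16m+1sm								
Paraphrynus_mexicanus	Paraphrynus mexicanus	Amblypygi	this_study+literature	24		both	11bi+1bi		XY_heteromorphic	1	NORperic				0
Paraphrynus_pseudomexicanus	Paraphrynus pseudomexicanus	Amblypygi	literature	32		male	8m+1sm+7a								
Paraphrynus_robustus	Paraphrynus robustus	Amblypygi	literature	64		male	16m+6sm+2st+8a								
Phrynus_marginemaculatus	Phrynus marginemaculatus	Amblypygi	literature	68		male	14m+5sm+5st+10a								
Hypoctonus_cf_gastrostictus	Hypoctonus cf. gastrostictus	Thelyphonida	this_study	66		male	22bi+2st+9a		none_detected	2	NORt;NORt		low_centromeric_telomeric		
Labochirus_proboscideus	Labochirus proboscideus	Thelyphonida	this_study	78		both	6m+2m/sm+3sm+28mono		none_detected				low_centromeric_telomeric		
Yekuana_venezolensis	Yekuana venezolensis	Thelyphonida	this_study	38		male	4m+1m/sm+4sm+1st+9a		none_detected	1	NORpt		low_centromeric_telomeric		
Mastigoproctus_giganteus	Mastigoproctus giganteus	Thelyphonida	this_study	28		both	7m+1sm+1sm/st+1st+4a		none_detected	2	NORt;NORt		low_centromeric_telomeric		
Uroproctus_assamensis	Uroproctus assamensis	Thelyphonida	this_study	72		both	4m+3sm+1sm/st+28mono		none_detected	3	NORt;NORt;NORt		low_centromeric_telomeric		
Ginosigma_sp	Ginosigma sp.	Thelyphonida	this_study	40		male	4m+4sm+1sm/st+4st+7a		none_detected	3	NORpt;NORpt;NORpt	TTAGG	low_centromeric_telomeric		
Thelyphonus_cf_linganus	Thelyphonus cf. linganus	Thelyphonida	this_study	66		both	19bi+3st+10a+1bi		XY_heteromorphic				low_centromeric_telomeric		
Thelyphonus_sepiaris	Thelyphonus sepiaris	Thelyphonida	literature	42	44	both	21a+1a		XY_heteromorphic				low_centromeric_telomeric		
Typopeltis_crucifer	Typopeltis crucifer	Thelyphonida	this_study	40		female									
Typopeltis_guangxiensis	Typopeltis guangxiensis	Thelyphonida	this_study	36		both	6m+4sm+1st+7a		none_detected	5	NORt;NORpt;NORqt;NORqt;NORqt		low_centromeric_telomeric		
Clavizomus_sp	Clavizomus sp.	Schizomida	this_study	22		male	1m+3st+7a		none_detected						
Notozomus_sp	Notozomus sp.	Schizomida	this_study	22		male	2st+9a		none_detected						
Orientzomus_Luzon	Orientzomus sp. (Luzon)	Schizomida	this_study	16		both	5bi+3a		none_detected						
Orientzomus_Mindanao	Orientzomus sp. (Mindanao)	Schizomida	this_study	16		female			none_detected	1	NORt				
Stenochrus_sp	Stenochrus sp.	Schizomida	this_study	22		both	8st+3a		none_detected			TTAGG			
Olmecazomus_brujo	Olmecazomus brujo	Schizomida	this_study	22		both	11a		none_detected	1	NORqi				
Rowlandius_ubajara	Rowlandius ubajara	Schizomida	literature	22		female	1m+10mono		none_detected						
Rowlandius_sp	Rowlandius sp.	Schizomida	literature	20		female	1m+9mono		none_detected						
Hubbardiidae_Seychelles	Hubbardiidae sp. (Seychelles)	Schizomida	this_study	22		juvenile	11a		none_detected	1	NORt				
Hubbardiidae_Cameroon	Hubbardiidae sp. (Cameroon)	Schizomida	this_study	22		juvenile	11a		none_detected	1	NORqi				
Agastoschizomus_lucifer	Agastoschizomus lucifer	Schizomida	this_study	22		female	11a		none_detected	1	NORt				
Cryptocellus_narino	Cryptocellus narino	Ricinulei	this_study	46		both	1m+1m/sm+2sm+1st+18a		none_detected	1	NORsubt			0	
Pseudocellus_gertschi	Pseudocellus gertschi	Ricinulei	this_study	40		both	2m+4sm+1sm/st+13mono		none_detected	1	NORqt	TTAGG		1	
Ricinoides_olounoua	Ricinoides olounoua	Ricinulei	this_study	40		male	16bi+4st		none_detected	1	NORsubt			1	
Ammotrechula_mulaiki	Ammotrechula mulaiki	Solifugae	this_study	24		both	2st+10a		none_detected						
Eberlanzia_flava	Eberlanzia flava	Solifugae	this_study	22		male	2m+2st+7a		none_detected	1	NORpt		low_centromeric_telomeric		
Gluvia_dorsalis	Gluvia dorsalis	Solifugae	this_study	10		both	5a		none_detected				low_centromeric_telomeric		
Gnosippus_sp	Gnosippus sp.	Solifugae	this_study	16		male		monop_predominant	none_detected						
Eremobates_pallipes	Eremobates pallipes	Solifugae	this_study	22		male	1m+2st+8a		none_detected	1	NORarm		low_centromeric_telomeric		
Eremobates_similis	Eremobates similis	Solifugae	this_study	22		male	1m+10a		none_detected	1	NORt		low_centromeric_telomeric		
Paragaleodes_pallidus	Paragaleodes pallidus	Solifugae	this_study	12		both	6m		none_detected	8	NORsubt;NORsubt;NORpsubt;NORqsubt;NORpsubt;NORqsubt;NORpsubt;NORqsubt		enormous_blocks		
Rhagodes_sp	Rhagodes sp.	Solifugae	this_study+literature	18		juvenile	7m+2st		none_detected			TTAGG	enormous_blocks		
Solpugista_sp	Solpugista sp.	Solifugae	this_study	20		female	10a		none_detected	1	NORt		low_centromeric_telomeric		
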