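# SINA/SIAH reference dataset: accession, species, paralog group (n=70).
# The P. marinus entry is a UniProtKB identifier; all others are NCBI.
# accession	species	group
NP_003022.3	Homo sapiens	SIAH1
NP_005058.3	Homo sapiens	SIAH2
NP_942146.2	Homo sapiens	SIAH3
NP_001233288.1	Pan troglodytes	SIAH1
XP_516819.2	Pan troglodytes	SIAH2
XP_522672.3	Pan troglodytes	SIAH3
NP_033198.1	Mus musculus	SIAH1
NP_033200.2	Mus musculus	SIAH2
NP_001121565.1	Mus musculus	SIAH3
XP_005218736.1	Bos taurus	SIAH1
NP_001193983.1	Bos taurus	SIAH2
NP_001192350.1	Bos taurus	SIAH3
XP_019788031.1	Tursiops truncatus	SIAH1
XP_019789908.1	Tursiops truncatus	SIAH2
XP_019792000.1	Tursiops truncatus	SIAH3
XP_007474893.1	Monodelphis domestica	SIAH1
XP_001363407.1	Monodelphis domestica	SIAH2
XP_007501643.1	Monodelphis domestica	SIAH3
XP_015147897.1	Gallus gallus	SIAH1
XP_426719.2	Gallus gallus	SIAH2
XP_417044.1	Gallus gallus	SIAH3
XP_014738058.1	Sturnus vulgaris	SIAH1
XP_014741604.1	Sturnus vulgaris	SIAH2
XP_014750862.1	Sturnus vulgaris	SIAH3
XP_020643987.1	Pogona vitticeps	SIAH1
XP_020637543.1	Pogona vitticeps	SIAH2
XP_013913965.1	Thamnophis sirtalis	SIAH1
XP_013927960.1	Thamnophis sirtalis	SIAH2
XP_019352994.1	Alligator mississippiensis	SIAH1
XP_006259223.1	Alligator mississippiensis	SIAH2
XP_019356083.1	Alligator mississippiensis	SIAH3
XP_008165194.1	Chrysemys picta	SIAH1
XP_005286979.1	Chrysemys picta	SIAH2
XP_005287220.1	Chrysemys picta	SIAH3
NP_001015836.1	Xenopus tropicalis	SIAH1
NP_001095281.1	Xenopus tropicalis	SIAH2
XP_002941011.1	Xenopus tropicalis	SIAH3
XP_005998413.1	Latimeria chalumnae	SIAH1
XP_006008925.1	Latimeria chalumnae	SIAH2
XP_014352065.1	Latimeria chalumnae	SIAH3
NP_955815.1	Danio rerio	SIAH1
NP_956721.2	Danio rerio	SIAH2
XP_013979721.1	Salmo salar	SIAH1
XP_014052924.1	Salmo salar	SIAH2
XP_019217515.1	Oreochromis niloticus	SIAH1
XP_003459581.3	Oreochromis niloticus	SIAH2
XP_007887616.1	Callorhinchus milii	SIAH1
XP_007889716.1	Callorhinchus milii	SIAH2
XP_007889930.1	Callorhinchus milii	SIAH3
S4R9G1_PETMA	Petromyzon marinus	SIAH1
XP_002609562.1	Branchiostoma floridae	SINA
XP_797311.2	Strongylocentrotus purpuratus	SINA
NP_476725.1	Drosophila melanogaster	SINA
XP_001688791.1	Anopheles gambiae	SINA
XP_394284.2	Apis mellifera	SINA
XP_008186354.1	Acyrthosiphon pisum	SINA
NP_500409.1	Caenorhabditis elegans	SINA
XP_013306181.1	Necator americanus	SINA
XP_001898781.1	Brugia malayi	SINA
XP_003379392.1	Trichinella spiralis	SINA
XP_014779248.1	Octopus bimaculoides	SINA
XP_011434753.1	Crassostrea gigas	SINA
XP_009028819.1	Helobdella robusta	SINA
XP_018646300.1	Schistosoma mansoni	SINA
XP_001637064.1	Nematostella vectensis	SINA
XP_020623250.1	Orbicella faveolata	SINA
XP_015766642.1	Acropora digitifera	SINA
XP_002162099.1	Hydra vulgaris	SINA
XP_019850617.1	Amphimedon queenslandica	SINA
XP_002108034.1	Trichoplax adhaerens	SINA
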