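species	gRNA_OXTR.1	gRNA_OXTR.2
Acomys russatus	No	Yes
Ailuropoda melanoleuca	No	Yes
Aotus nancymaae	No	Yes
Apodemus sylvaticus	No	Yes
Arvicanthis niloticus	Yes	No
Arvicola amphibius	Yes	Yes
Balaenoptera acutorostrata scammoni	No	Yes
Balaenoptera musculus	No	Yes
Callithrix jacchus	No	Yes
Canis lupus dingo	No	Yes
Canis lupus familiaris	No	Yes
Cavia porcellus	No	Yes
Cebus imitator	No	Yes
Ceratotherium simum simum	No	Yes
Choloepus didactylus	No	Yes
Chrysochloris asiatica	No	Yes
Cricetulus griseus	Yes	Yes
Dipodomys ordii	No	Yes
Dipodomys spectabilis	No	Yes
Echinops telfairi	No	Yes
Elephantulus edwardii	No	Yes
Elephas maximus indicus	No	Yes
Eptesicus fuscus	No	Yes
Equus asinus	No	Yes
Equus caballus	No	Yes
Equus przewalskii	No	Yes
Equus quagga	No	Yes
Erinaceus europaeus	No	Yes
Fukomys damarensis	No	Yes
Galeopterus variegatus	No	Yes
Globicephala melas	No	Yes
Grammomys surdaster	Yes	Yes
Heterocephalus glaber	No	Yes
Hipposideros armiger	No	Yes
Jaculus jaculus	No	Yes
Lagenorhynchus obliquidens	No	Yes
Lemur catta	No	Yes
Lipotes vexillifer	No	Yes
Manis javanica	No	Yes
Manis pentadactyla	No	Yes
Mastomys coucha	Yes	Yes
Meles meles	No	Yes
Meriones unguiculatus	Yes	Yes
Mesocricetus auratus	Yes	Yes
Microcebus murinus	No	Yes
Microtus fortis	Yes	Yes
Microtus ochrogaster	Yes	Yes
Microtus oregoni	No	Yes
Miniopterus natalensis	No	Yes
Monodon monoceros	No	Yes
Mus caroli	Yes	Yes
Mus musculus	Yes	Yes
Mus pahari	Yes	Yes
Mustela erminea	No	Yes
Myodes glareolus	Yes	Yes
Myotis brandtii	No	Yes
Myotis davidii	No	Yes
Myotis lucifugus	No	Yes
Myotis myotis	No	Yes
Nannospalax galili	No	Yes
Neophocaena asiaeorientalis asiaeorientalis	No	Yes
Ochotona princeps	No	Yes
Onychomys torridus	No	Yes
Orcinus orca	No	Yes
Oryctolagus cuniculus	No	Yes
Otolemur garnettii	No	Yes
Peromyscus californicus insignis	Yes	Yes
Peromyscus leucopus	Yes	Yes
Peromyscus maniculatus bairdii	Yes	Yes
Phocoena sinus	No	Yes
Phodopus roborovskii	Yes	Yes
Pipistrellus kuhlii	No	Yes
Propithecus coquereli	No	Yes
Rattus norvegicus	Yes	Yes
Rattus rattus	Yes	Yes
Rhinolophus ferrumequinum	No	Yes
Rhinolophus sinicus	No	Yes
Saimiri boliviensis boliviensis	No	Yes
Sapajus apella	No	Yes
Talpa occidentalis	No	Yes
Trichechus manatus latirostris	No	Yes
Tupaia chinensis	No	Yes
Tursiops truncatus	Yes	Yes
Ursus americanus	No	Yes
Ursus arctos	No	Yes
Ursus maritimus	No	Yes
Vulpes lagopus	No	Yes
Vulpes vulpes	No	Yes
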