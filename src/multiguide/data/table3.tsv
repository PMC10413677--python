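species	gRNA_OXTR.1	gRNA_OXTR.2
Acinonyx jubatus	No	Yes
Ailuropoda melanoleuca	No	Yes
Aotus nancymaae	No	Yes
Artibeus jamaicensis	No	Yes
Balaenoptera acutorostrata scammoni	No	Yes
Balaenoptera musculus	No	Yes
Bison bison bison	No	Yes
Bos indicus	No	Yes
Bos indicus × Bos taurus	No	Yes
Bos mutus	No	Yes
Bos taurus	No	Yes
Bubalus bubalis	No	Yes
Budorcas taxicolor	No	Yes
Callorhinus ursinus	No	Yes
Camelus bactrianus	No	Yes
Camelus dromedarius	No	Yes
Camelus ferus	No	Yes
Capra hircus	No	Yes
Cebus imitator	No	Yes
Cercocebus atys	No	Yes
Cervus canadensis	No	Yes
Cervus elaphus	No	Yes
Chlorocebus sabaeus	No	Yes
Choloepus didactylus	No	Yes
Colobus angolensis palliatus	No	Yes
Dasypus novemcinctus	No	Yes
Delphinapterus leucas	No	Yes
Echinops telfairi	No	Yes
Enhydra lutris kenyoni	No	Yes
Eptesicus fuscus	No	Yes
Equus asinus	No	Yes
Equus caballus	No	Yes
Equus przewalskii	No	Yes
Equus quagga	No	Yes
Erinaceus europaeus	No	Yes
Eumetopias jubatus	No	Yes
Felis catus	No	Yes
Globicephala melas	No	Yes
Gorilla gorilla gorilla	No	Yes
Halichoerus grypus	No	Yes
Homo sapiens	No	Yes
Hyaena hyaena	No	Yes
Hylobates moloch	No	Yes
Lagenorhynchus obliquidens	No	Yes
Lemur catta	No	Yes
Leopardus geoffroyi	No	Yes
Leptonychotes weddellii	No	Yes
Lipotes vexillifer	No	Yes
Lontra canadensis	No	Yes
Lutra lutra	No	Yes
Lynx canadensis	No	Yes
Lynx rufus	No	Yes
Macaca fascicularis	No	Yes
Macaca mulatta	No	Yes
Macaca nemestrina	No	Yes
Macaca thibetana thibetana	No	Yes
Mandrillus leucophaeus	No	Yes
Manis pentadactyla	No	Yes
Meles meles	No	Yes
Microcebus murinus	No	Yes
Miniopterus natalensis	No	Yes
Mirounga angustirostris	No	Yes
Mirounga leonina	No	Yes
Monodon monoceros	No	Yes
Mustela erminea	No	Yes
Mustela putorius furo	No	Yes
Myotis brandtii	No	Yes
Myotis lucifugus	No	Yes
Myotis myotis	No	Yes
Nannospalax galili	No	Yes
Neogale vison	No	Yes
Neomonachus schauinslandi	No	Yes
Neophocaena asiaeorientalis asiaeorientalis	No	Yes
Nomascus leucogenys	No	Yes
Odobenus rosmarus divergens	No	Yes
Odocoileus virginianus texanus	No	Yes
Orcinus orca	No	Yes
Oryx dammah	No	Yes
Ovis aries	No	Yes
Pan paniscus	No	Yes
Pan troglodytes	No	Yes
Panthera leo	No	Yes
Panthera pardus	No	Yes
Panthera tigris	No	Yes
Panthera uncia	No	Yes
Papio anubis	No	Yes
Phacochoerus africanus	No	Yes
Phoca vitulina	No	Yes
Phocoena sinus	No	Yes
Phyllostomus discolor	No	Yes
Phyllostomus hastatus	No	Yes
Physeter catodon	No	Yes
Piliocolobus tephrosceles	No	Yes
Pipistrellus kuhlii	No	Yes
Pongo abelii	No	Yes
Prionailurus bengalensis	No	Yes
Prionailurus viverrinus	No	Yes
Propithecus coquereli	No	Yes
Pteropus alecto	No	Yes
Pteropus giganteus	No	Yes
Pteropus vampyrus	No	Yes
Puma concolor	No	Yes
Puma yagouaroundi	No	Yes
Rhinolophus ferrumequinum	No	Yes
Rhinolophus sinicus	No	Yes
Rhinopithecus bieti	No	Yes
Rhinopithecus roxellana	No	Yes
Rousettus aegyptiacus	No	Yes
Saimiri boliviensis boliviensis	No	Yes
Sapajus apella	No	Yes
Sturnira hondurensis	No	Yes
Suncus etruscus	No	Yes
Sus scrofa	No	Yes
Talpa occidentalis	No	Yes
Theropithecus gelada	No	Yes
Trachypithecus francoisi	No	Yes
Tupaia chinensis	No	Yes
Tursiops truncatus	No	Yes
Ursus americanus	No	Yes
Ursus arctos	No	Yes
Ursus arctos horribilis	No	Yes
Ursus maritimus	No	Yes
Vicugna pacos	No	Yes
Zalophus californianus	No	Yes
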