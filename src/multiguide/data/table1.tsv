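species	gRNA_OXTR.1	gRNA_OXTR.2
Acomys cahirinus	No	Yes
Acomys russatus	No	Yes
Apodemus speciosus	No	Yes
Apodemus sylvaticus	No	Yes
Arvicanthis niloticus	Yes	No
Arvicola amphibius	Yes	Yes
Capromys pilorides	No	Yes
Cavia aperea	No	Yes
Cavia porcellus	No	Yes
Cavia tschudii	No	Yes
Cricetomys gambianus	No	Yes
Cricetulus griseus	Yes	Yes
Dasyprocta punctata	No	Yes
Dinomys branickii	No	Yes
Dipodomys ordii	No	Yes
Dipodomys spectabilis	No	Yes
Dipodomys stephensi	No	Yes
Dolichotis patagonum	No	Yes
Ellobius lutescens	Yes	Yes
Ellobius talpinus	Yes	Yes
Erethizon dorsatum	No	Yes
Fukomys damarensis	No	Yes
Glis glis	No	Yes
Grammomys surdaster	Yes	Yes
Heterocephalus glaber	No	Yes
Hydrochoerus hydrochaeris	No	Yes
Hylomyscus alleni	Yes	Yes
Hystrix brachyura	No	Yes
Hystrix cristata	No	Yes
Jaculus jaculus	No	Yes
Lophiomys imhausi	No	Yes
Mastomys coucha	Yes	Yes
Mastomys natalensis	Yes	Yes
Meriones unguiculatus	Yes	Yes
Mesocricetus auratus	Yes	Yes
Microtus agrestis	Yes	Yes
Microtus arvalis	No	Yes
Microtus fortis	Yes	Yes
Microtus montanus	Yes	Yes
Microtus ochrogaster	Yes	Yes
Microtus oeconomus	Yes	Yes
Microtus oregoni	No	Yes
Microtus richardsoni	Yes	Yes
Mus caroli	Yes	Yes
Mus minutoides	Yes	Yes
Mus musculus	Yes	Yes
Mus pahari	Yes	Yes
Mus spicilegus	Yes	Yes
Mus spretus	Yes	Yes
Muscardinus avellanarius	No	Yes
Myocastor coypus	No	Yes
Myodes glareolus	Yes	Yes
Nannospalax galili	No	Yes
Neotoma lepida	Yes	Yes
Ondatra zibethicus	Yes	Yes
Onychomys torridus	No	Yes
Orientallactaga bullata	No	Yes
Pedetes capensis	No	Yes
Peromyscus attwateri	Yes	Yes
Peromyscus aztecus	Yes	Yes
Peromyscus californicus	Yes	Yes
Peromyscus eremicus	Yes	Yes
Peromyscus leucopus	Yes	Yes
Peromyscus maniculatus	Yes	Yes
Peromyscus melanophrys	Yes	Yes
Peromyscus nudipes	Yes	Yes
Peromyscus polionotus	Yes	Yes
Phodopus roborovskii	Yes	Yes
Phodopus sungorus	No	Yes
Praomys delectorum	Yes	Yes
Psammomys obesus	Yes	Yes
Rattus norvegicus	Yes	Yes
Rattus rattus	Yes	Yes
Rhabdomys dilectus	Yes	Yes
Rhizomys pruinosus	No	Yes
Rhombomys opimus	Yes	Yes
Rhynchomys soricoides	Yes	Yes
Sigmodon hispidus	No	Yes
Thryonomys swinderianus	No	Yes
Typhlomys cinereus	No	Yes
Zapus hudsonius	No	Yes
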