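name,group,aliases
Aspergillus flavus,1,
Aspergillus fumigatus,1,
Aspergillus niger,1,
Aspergillus ochraceus,1,
Aspergillus penicillioides,1,
Aspergillus restrictus,1,
Aspergillus sclerotiorum,1,
Aspergillus sydowii,1,
Aspergillus unguis,1,
Aspergillus versicolor,1,
Aureobasidium pullulans,1,
Chaetomium globosum,1,
Cladosporium sphaerospermum,1,
Eurotium group,1,Eurotium amstelodami
Paecilomyces variotii,1,
Penicillium brevicompactum,1,
Penicillium corylophilum,1,
Penicillium crustosum,1,Penicillium Group 2;Penicillium crustosum group 2
Penicillium purpurogenum,1,
Penicillium spinulosum,1,
Penicillium variabile,1,
Scopulariopsis brevicaulis,1,
Scopulariopsis chartarum,1,
Stachybotrys chartarum,1,
Trichoderma viride,1,
Wallemia sebi,1,
Acremonium strictum,2,
Alternaria alternata,2,
Aspergillus ustus,2,
Cladosporium cladosporioides 1,2,Cladosporium cladosporioides (Type 1);Cladosporium cladosporioides Type 1
Cladosporium cladosporioides 2,2,Cladosporium cladosporioides (Type 2);Cladosporium cladosporioides Type 2
Cladosporium herbarum,2,
Epicoccum nigrum,2,
Mucor group,2,Mucor racemosus
Penicillium chrysogenum 2,2,Penicillium chrysogenum (Type 2);Penicillium chrysogenum Type 2
Rhizopus stolonifer,2,
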