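species,cluster,group,r2_own,r2_next
Aspergillus ochraceus,1,1,0.340,0.096
Aspergillus penicillioides,1,1,0.475,0.166
Aspergillus restrictus,1,1,0.317,0.034
Aspergillus sclerotiorum,1,1,0.353,0.048
Aspergillus versicolor,1,1,0.379,0.098
Scopulariopsis chartarum,1,1,0.361,0.129
Wallemia sebi,1,1,0.509,0.141
Chaetomium globosum,2,1,0.514,0.148
Cladosporium sphaerospermum,2,1,0.535,0.211
Penicillium crustosum,2,1,0.198,0.053
Trichoderma viride,2,1,0.478,0.116
Aspergillus fumigatus,3,1,0.325,0.133
Paecilomyces variotii,3,1,0.474,0.102
Penicillium brevicompactum,3,1,0.473,0.204
Penicillium corylophilum,3,1,0.374,0.079
Penicillium variabile,3,1,0.415,0.172
Penicillium purpurogenum,4,1,1.000,0.028
Acremonium strictum,5,2,0.543,0.109
Alternaria alternata,5,2,0.576,0.137
Cladosporium cladosporioides 1,5,2,0.755,0.310
Cladosporium cladosporioides 2,5,2,0.478,0.229
Cladosporium herbarum,5,2,0.507,0.121
Epicoccum nigrum,5,2,0.648,0.349
Aspergillus flavus,6,1,0.299,0.013
Aspergillus niger,6,1,0.429,0.090
Aspergillus sydowii,6,1,0.375,0.059
Aspergillus unguis,6,1,0.499,0.087
Penicillium spinulosum,6,1,0.145,0.030
Aspergillus ustus,6,2,0.433,0.127
Penicillium chrysogenum 2,6,2,0.429,0.133
Aureobasidium pullulans,7,1,0.326,0.177
Eurotium group,7,1,0.538,0.283
Scopulariopsis brevicaulis,7,1,0.547,0.173
Stachybotrys chartarum,7,1,0.429,0.163
Mucor group,7,2,0.469,0.179
Rhizopus stolonifer,7,2,0.348,0.060
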