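response,z_lon,p_lon,p_lon_censored,z_lat,p_lat,p_lat_censored
Aspergillus flavus,-2.374,0.018,0,1.437,0.151,0
Aspergillus fumigatus,-0.985,0.325,0,1.476,0.140,0
Aspergillus niger,-5.152,0.0005,1,4.537,0.0005,1
Aspergillus ochraceus,-1.392,0.164,0,2.127,0.033,0
Aspergillus penicillioides,1.019,0.308,0,0.163,0.871,0
Aspergillus restrictus,1.705,0.088,0,-1.271,0.204,0
Aspergillus sclerotiorum,1.530,0.126,0,-1.522,0.128,0
Aspergillus sydowii,0.499,0.618,0,-1.266,0.205,0
Aspergillus unguis,0.067,0.946,0,-0.341,0.733,0
Aspergillus versicolor,2.801,0.005,0,-2.165,0.030,0
Aureobasidium pullulans,-3.217,0.001,0,3.662,0.0005,1
Chaetomium globosum,1.243,0.214,0,1.087,0.277,0
Cladosporium sphaerospermum,0.852,0.394,0,-0.663,0.507,0
Eurotium group,-3.332,0.0005,1,4.836,0.0005,1
Paecilomyces variotii,0.629,0.529,0,-0.232,0.817,0
Penicillium brevicompactum,-2.970,0.003,0,3.289,0.001,0
Penicillium corylophilum,-2.104,0.035,0,2.751,0.006,0
Penicillium crustosum,-1.303,0.193,0,1.734,0.083,0
Penicillium purpurogenum,-0.044,0.965,0,-0.408,0.683,0
Penicillium spinulosum,-1.607,0.108,0,1.695,0.090,0
Penicillium variabile,3.012,0.003,0,-2.72,0.006,0
Scopulariopsis brevicaulis,-0.450,0.653,0,1.019,0.308,0
Scopulariopsis chartarum,-1.835,0.067,0,2.647,0.008,0
Stachybotrys chartarum,-3.296,0.0005,1,3.192,0.001,0
Trichoderma viride,3.636,0.0005,1,-3.413,0.0005,1
Wallemia sebi,4.215,0.0005,1,-3.720,0.0005,1
Acremonium strictum,-0.168,0.866,0,2.108,0.0005,1
Alternaria alternata,-8.768,0.0005,1,9.706,0.0005,1
Aspergillus ustus,-2.878,0.004,0,2.451,0.014,0
Cladosporium cladosporioides 1,-0.472,0.637,0,1.952,0.051,0
Cladosporium cladosporioides 2,-8.110,0.0005,1,9.179,0.0005,1
Cladosporium herbarum,-6.994,0.0005,1,8.957,0.0005,1
Epicoccum nigrum,0.510,0.610,0,1.504,0.133,0
Mucor group,4.648,0.0005,1,-3.985,0.0005,1
Penicillium chrysogenum 2,-3.456,0.0005,1,3.935,0.0005,1
Rhizopus stolonifer,-2.743,0.006,0,2.659,0.008,0
SLG1,-0.372,0.710,0,1.067,0.286,0
SLG2,-3.878,0.0005,1,5.599,0.0005,1
ERMI,2.538,0.011,0,-2.953,0.003,0
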