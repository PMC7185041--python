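species_code,common_name,n_stations,n_year_inds,n_SY,n_ASY,n_AHY,error_rate,n_eligible,yearling_prop
YBSA,Yellow-bellied sapsucker,33,267,132,120,15,0.056,178,0.524
ALFL,Alder flycatcher,36,845,166,573,106,0.119,345,0.225
LEFL,Least flycatcher,35,517,209,252,56,0.086,163,0.453
REVI,Red-eyed vireo,31,507,78,360,69,0.042,143,0.178
BCCH,Black-capped chickadee,29,190,48,62,80,0.071,99,0.436
RCKI,Ruby-crowned kinglet,18,155,48,62,45,0.021,47,0.436
SWTH,Swainson's thrush,36,747,276,356,115,0.046,263,0.437
AMRO,American robin,35,471,204,210,57,0.132,151,0.493
CEDW,Cedar waxwing,27,358,142,191,25,0.017,60,0.426
CHSP,Chipping sparrow,38,801,302,427,72,0.080,224,0.414
CCSP,Clay-colored sparrow,23,755,299,399,57,0.128,344,0.428
SAVS,Savannah sparrow,5,266,71,179,16,0.140,136,0.284
SOSP,Song sparrow,15,141,39,88,14,0.134,97,0.307
LISP,Lincoln's sparrow,35,546,203,277,66,0.180,417,0.423
SWSP,Swamp sparrow,23,216,119,75,22,0.088,159,0.613
WTSP,White-throated sparrow,37,1474,450,853,171,0.089,1093,0.345
OVEN,Ovenbird,37,567,212,278,77,0.084,178,0.433
NOWA,Northern waterthrush,19,127,19,88,20,0.061,66,0.178
BAWW,Black-and-white warbler,30,261,117,113,31,0.026,77,0.509
TEWA,Tennessee warbler,37,2399,968,1148,283,0.055,660,0.457
MOWA,Mourning warbler,20,220,73,130,17,0.077,195,0.360
COYE,Common yellowthroat,28,236,67,145,24,0.081,111,0.316
AMRE,American redstart,22,214,85,106,23,0.049,81,0.445
MAWA,Magnolia warbler,27,292,143,133,16,0.073,219,0.518
YEWA,Yellow warbler,21,309,106,167,36,0.041,197,0.388
YRWA,Yellow-rumped warbler,29,278,124,137,17,0.194,93,0.475
CAWA,Canada warbler,22,304,129,121,54,0.133,165,0.516
WIWA,Wilson's warbler,28,193,70,93,30,0.132,91,0.429
RBGR,Rose-breasted grosbeak,22,134,44,81,9,0.000,33,0.352
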