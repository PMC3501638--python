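taxon,localities,specimens,MAT_L,MAT_S,MxTWM_L,MxTWM_S,MnTCM_L,MnTCM_S,MAP_L,MAP_S,PWM_L,PWM_S,PDM_L,PDM_S
Acomys,66,232,19.0,18.3,29.8,29.3,5.2,4.9,559,556,101,95,9,12
Aethomys,339,1485,19.5,19.0,29.6,29.7,5.5,4.8,687,657,124,119,9,9
Bathyergus,18,89,17.0,17.3,27.5,27.4,7.1,7.4,383,355,61,53,12,14
Cricetomys,8,30,18.9,18.1,28.0,27.0,5.8,5.3,879,945,178,194,10,11
Cryptomys,200,915,17.6,17.7,28.6,28.3,3.5,3.3,666,710,116,126,10,10
Dasymys,26,72,18.7,18.7,28.3,28.3,5.6,5.5,802,801,137,148,13,12
Dendromus,108,251,17.6,17.4,27.8,27.1,4.5,5.2,749,825,125,132,14,17
Desmodillus,66,415,18.0,17.6,32.5,32.5,2.3,1.3,278,325,49,57,6,7
Georhychus,23,83,15.7,16.6,26.6,28.3,4.4,5.0,717,600,108,89,24,19
Gerbilliscus,357,1908,19.2,19.5,30.2,30.8,4.4,4.6,594,562,109,103,6,7
Gerbillurus,85,964,18.0,18.3,31.5,32.5,3.7,3.2,260,230,47,42,5,5
Grammomys,35,88,18.8,18.5,27.4,26.6,7.6,7.8,885,961,142,156,20,20
Graphiurus,141,261,17.9,17.5,28.1,27.8,4.0,3.9,715,724,126,125,10,11
Hystrix,15,17,18.1,18.1,30.5,30.8,3.0,2.8,491,478,87,85,8,8
Lemniscomys,139,341,19.8,19.9,29.9,30.0,5.7,5.7,682,676,123,123,8,8
Malacothrix,29,155,16.6,16.4,30.7,30.5,0.6,0.7,445,438,77,74,8,9
Mastomys,478,3331,18.5,18.1,29.0,28.8,4.3,3.9,695,708,123,123,9,10
Micaelamys,286,2105,18.2,18.1,29.7,30.8,3.9,3.3,565,441,102,79,7,7
Mus,233,659,18.0,17.7,28.7,28.4,4.3,4.6,665,692,112,110,12,15
Myomyscus,28,276,16.0,15.6,27.1,26.8,5.3,4.9,647,646,82,78,33,35
Myotomys,42,226,16.3,16.0,29.1,28.1,3.4,3.7,273,248,45,42,7,6
Mystromys,39,117,15.9,15.9,28.0,28.4,0.9,0.9,649,646,110,107,10,11
Otomys,263,1103,17.0,16.5,27.4,26.9,3.5,3.2,740,747,126,127,12,14
Paraxerus,63,155,20.6,21.2,30.9,31.5,6.3,7.0,577,549,111,106,5,5
Parotomys,19,123,17.6,17.6,31.9,30.8,2.7,4.3,198,184,37,33,5,4
Pedetes,62,119,18.1,17.9,30.1,30.0,2.4,1.9,528,536,97,98,5,5
Petromus,9,39,18.2,17.7,31.6,30.8,5.4,5.2,149,156,25,25,4,4
Petromyscus,16,102,17.8,20.6,32.2,36.0,3.5,4.9,207,120,34,22,7,4
Rhabdomys,311,2712,16.7,16.3,28.2,27.7,2.6,2.8,624,604,107,102,10,11
Saccostomus,191,611,19.8,19.6,31.0,31.2,5.3,5.2,580,552,103,97,9,10
Steatomys,75,185,19.1,19.1,29.5,29.5,5.1,5.1,682,704,123,130,8,9
Thallomys,57,179,19.6,19.5,30.5,31.3,4.5,3.4,616,527,115,97,7,5
Thryonomys,21,30,19.0,19.4,28.9,29.3,5.3,5.8,753,762,133,135,11,12
Xerus,33,99,17.4,17.6,31.1,31.4,0.8,0.4,451,463,79,80,6,6
Zelotomys,1,1,17.6,17.6,31.9,31.9,1.0,1.0,473,473,85,85,3,3
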