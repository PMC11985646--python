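id,printed_no,rt_min,name,formula,polarity,precursor_mz,other_mode_mz,error_ppm_printed,ms2,note
1,1,4.80,Hesperidin,C28H34O15,negative,609.1324,,0.3,463 301 177 151,
2,2,4.86,Kaempferol-O-hexuronide,C21H18O12,negative,461.0770,,0.1,285 257 135,
3,3,5.09,Quercetin-O-hexuronide,C21H18O13,negative,477.0676,479.1381,-6.6,301 179 151,
4,4,5.33,Luteolin-di-O-hexoside,C27H30O16,negative,609.1437,611.1800,8.6,447 285 151,
5,5,5.38,Luteolin-C-hexoside,C21H20O11,negative,447.0947,,-2.9,357 327 285 151 135,
6,6,5.52,Baicalein-O-hexuronide,C21H18O11,negative,445.0770,447.1028,2.2,269 117,
7,7,5.64,Quercetin-O-di-hexoside,C27H30O17,negative,625.1737,627.2105,6.1,463 301 283,
8,8,6.18,Isoquercitrin,C21H20O12,negative,463.0918,,0.5,301 283 255 151,
9,9,6.41,Apigenin-C-hexoside,C21H20O10,positive,433.1357,,0.2,343 313 271,
10,10,6.48,Rutin,C27H30O16,positive,611.1806,,2.2,465 303,
11,11,6.50,Eriodictyol-O-hexoside,C21H22O11,negative,449.1194,,0.7,287 151 135,
12,12,6.52,Hyperoside,C21H20O12,negative,463.0938,465.1223,0.8,301 271 255 151,
13,13,6.57,Apigenin-O-hexoside,C21H20O10,negative,431.0989,433.1263,-9.5,269,
14,14,6.59,Maritimetin-O-hexoside,C21H20O11,negative,447.0909,449.1236,4.2,285,
15,15,6.59,Kaempferol-O-neohesperidoside,C27H30O15,negative,593.1467,,0.3,285,
16,16,6.62,Kaempferol-O-bis-deoxyhexoside,C27H30O14,negative,577.1507,579.1816,6.7,431 285,
17,17,6.66,Luteolin-O-hexoside,C21H20O11,negative,447.0921,,2.7,285,
18,18,6.66,Isorhamnetin-O-deoxyhexosyl-hexoside,C28H32O16,negative,623.1590,625.1852,-0.2,315 300,
19,19,6.79,Okanin-O-hexoside,C21H22O11,negative,451.1404,,-0.7,289 271 179 163 153,
20,20,6.91,Naringenin-O-hexoside,C21H22O10,negative,433.1115,435.1358,4.5,271 151 119,
21,21,7.10,Vitexin-O-deoxyhexoside,C27H30O14,negative,577.1575,,-3.8,431 269,
22,22,7.16,Gossypin,C21H20O13,negative,479.1038,,3.8,317,
23,23,7.27,Syringetin-O-hexoside,C23H24O13,negative,507.1129,509.1445,-15.4,492 345,
24,23,7.30,Quercetin-O-hexoside,C21H20O12,negative,463.1217,465.1522,0.4,301 283 135,duplicate printed row number kept; resolved by row order
25,25,7.46,Kaempferol-O-pentoside,C20H18O10,positive,419.1226,,-2.5,287 259 231,printed under the deprotonated column but fragment arithmetic is protonated; transcribed as positive
26,26,7.46,Quercetin-O-hexosyl-pentoside,C26H28O16,positive,597.1898,,-10.6,435 303,
27,27,7.54,Isorhamnetin-O-hexoside,C22H22O12,negative,477.1333,,4.9,315 300 151,
28,28,7.89,Phlorizin,C21H24O10,negative,435.1261,,6.6,273 151 119,
29,29,8.63,Quercetin-O-pentoside,C20H18O11,negative,433.1016,435.0974,8.7,301 193 161 151,
30,30,8.66,Eriodictyol,C15H12O6,negative,287.0629,289.0796,0.5,213 151 135 107,
31,31,8.83,Acacetin-O-rutinoside,C28H32O14,negative,591.1729,,-1.2,283 268,
32,32,8.95,Kaempferol-O-(p-coumaroyl)-hexoside,C30H26O13,negative,593.1296,,-0.5,447 285,
33,33,9.22,Quercetin,C15H10O7,negative,301.0233,303.0576,1.5,255 193 151 135 121,
34,34,10.13,Apigenin,C15H10O5,negative,269.0447,271.0641,-3.2,159 151 133 117,
35,35,10.31,Hesperetin,C16H14O6,negative,301.0724,303.0969,-0.4,286 151 134,
36,36,10.34,Luteolin,C15H10O6,negative,285.0397,287.0589,3.3,257 177 151 133 107,
37,37,10.56,Trihydroxy-methoxyflavone,C16H12O6,negative,299.0556,,-1.7,284 256 151,
38,38,13.16,Acacetin,C16H12O5,negative,283.0606,285.0812,0.4,268 151 131,
39,39,13.43,Isorhamnetin,C16H12O7,negative,315.0881,317.0760,6.8,300 269 151 107,
40,40,14.35,Naringenin,C15H12O5,negative,271.0979,273.0861,2.4,225 136 122,
41,41,19.81,Rhamnetin,C16H12O7,positive,317.1220,,6.1,299,
42,42,19.82,Kaempferide,C16H12O6,positive,301.1492,,0.8,,
43,43,1.24,Gentisic acid,C7H6O4,negative,153.0193,,0.8,109 91,
44,44,1.24,Caffeic acid,C9H8O4,negative,179.0550,,-0.6,161 135,
45,45,1.73,Chlorogenic acid,C16H18O9,negative,353.0866,355.1069,3.1,191 179 161 135,
46,46,2.52,Homogenentisic acid,C8H8O4,negative,167.0331,,0.5,149 123 108,
47,47,2.77,Hydroxybenzoic acid,C7H6O3,negative,137.0242,,4.4,93 75,
48,48,3.37,Coumaric acid,C9H8O3,negative,163.0233,165.0931,0.2,119 101,
49,49,4.26,Protocatechuic acid,C7H6O4,negative,153.0183,,-4.3,135 109 91,
50,50,4.82,Dihydroxymandelate,C8H8O5,negative,183.0079,184.9872,24.8,139 109,
51,51,5.24,Sinapic acid-O-hexoside,C17H22O10,negative,385.1803,,8.4,223 205,
52,52,6.50,Methoxysalicylic acid,C8H8O4,negative,167.0341,,2,152 123 108,
53,53,8.40,Ferulic acid,C10H10O4,negative,193.0501,195.1168,1.4,178 161 149 133,
54,54,1.27,Hydroxy-Methylcoumarin,C10H8O3,negative,175.0423,,7.9,157 131 113,
55,55,2.68,Esculin,C15H16O9,negative,339.0741,341.0936,-3,177 133,
56,56,4.68,Dihydroxycoumarin,C9H6O4,negative,177.0187,179.0312,0.9,149 133 105,
57,57,7.09,Scopoletin,C10H8O4,negative,193.0547,,-7.1,178,
58,58,1.01,Malic acid,C4H6O5,negative,133.0145,,-0.9,115 89 71,
59,59,1.04,Maleic acid,C4H4O4,negative,115.0022,,9.3,71,
60,60,1.06,Hydroxy-butyric acid,C4H8O3,negative,103.0020,,9.4,59,
61,61,1.07,Lactic acid,C3H6O3,negative,89.02383,,-0.6,71,
62,62,1.11,Succinic acid,C4H6O4,negative,117.0177,,9,99 73,
63,63,1.15,Citrate,C6H8O7,negative,191.0556,,-0.3,173 129 111 85,
64,64,1.19,Tartrate,C4H6O6,negative,149.0448,,3.2,131 89 87,
65,65,1.25,Citramalate,C5H8O5,negative,146.9487,,3.6,129 85,
66,66,1.28,Isopropylmalic acid,C7H12O5,negative,175.0605,,-1,157 131 113 69,
67,67,1.35,Methylglutaric acid,C6H10O4,negative,145.0258,,13.1,127 109 101,
68,68,2.27,Phenyllactic acid,C9H10O3,negative,165.0562,,1,147 121 103,
69,69,4.90,Quinic acid,C7H12O6,negative,191.0559,,0.9,173 127 93,
70,70,5.09,Shikimic acid,C7H10O5,negative,173.0432,,-4.3,155 137 131 111 93,
71,71,1.11,Arginine,C6H14N4O2,positive,175.1210,,-4.3,,
72,72,1.55,Oxoproline,C5H7NO3,positive,130.0488,,3.9,,
73,73,1.71,Hydroxyproline,C5H9NO3,negative,130.0862,,4.2,,
74,74,2.15,Phenylalanine,C9H11NO2,positive,166.0876,,-0.6,,
75,75,2.80,Tryptophan,C11H12N2O2,negative,203.0821,,1.3,,
76,76,3.94,Homoisoleucine,C7H15NO2,negative,144.0459,,0.8,,
77,77,12.82,Hydroxy-hexadecanoic acid,C16H32O3,negative,271.2264,,9.1,253 212,
78,78,18.48,Linolenic acid,C18H30O2,negative,277.2177,,0.5,233,
79,79,1.36,Mannitol,C6H14O6,negative,181.0724,,-0.8,,
80,80,2.23,Maltitol,C12H24O11,negative,343.1402,,-0.5,,
81,81,2.46,Maltotriose,C18H32O16,negative,503.1371,,3.8,341 179,
82,82,3.82,Melibiose,C12H22O11,negative,341.0872,,7.6,,
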