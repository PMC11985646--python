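rt_min,name,formula,area_pct,curated_category
26.20,"Palmitic acid, methyl ester",C17H34O2,2.55,
26.96,Palmitic acid,C16H32O2,3.59,
29.33,"Linoleic acid, methyl ester",C19H34O2,1.32,
29.47,"Oleic acid, methyl ester",C19H36O2,4.45,
29.66,Tetramethyl-hexadecenol,C20H40O,1.14,other
29.66,Methyl-octadecadienol,C19H36O,1.14,other
29.99,"Stearic acid, methyl ester",C19H38O2,1.11,
30.22,Oleic acid,C18H34O2,5.03,
30.67,Stearic acid,C18H36O2,1.44,
32.77,Stigmasterol,C29H48O,3.34,sterol
38.41,Stigmastanol,C29H52O,0.67,sterol
38.89,Heptatriacotanol,C37H76O,1.03,other
39.68,Stigmastadiene-3-one,C29H46O,3.23,sterol
39.97,"lupene-3,28-diol/betulin",C30H50O2,24.95,sterol
40.65,Linoleic acid ethyl ester,C20H36O2,0.58,
41.06,Sitostenone,C29H48O,6.17,sterol
41.28,"Cyclolanostan-3-ol, acetate",C32H54O2,1.56,sterol
41.63,Tocopherol,C29H50O2,1.48,other
42.68,Ethyl iso-allocholate,C26H44O5,1.81,other
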