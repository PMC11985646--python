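# Principal-isotope exact masses (Da), CODATA/IUPAC atomic mass evaluation.
# version: 1.0
# columns: element	mass_number	exact_mass
H	1	1.00782503207
C	12	12.0
N	14	14.0030740048
O	16	15.9949146196
S	32	31.97207100
P	31	30.97376163
Na	23	22.9897692809
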