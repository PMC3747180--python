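# Stable-isotope masses (Da) and natural abundances (fraction) for the
# elements occurring in unmodified peptides.  Abundances per element sum to 1.
# columns: element	mass	abundance
H	1.00782503207	0.999885
H	2.01410177785	0.000115
C	12.0	0.9893
C	13.00335483781	0.0107
N	14.00307400478	0.99636
N	15.00010889823	0.00364
O	15.99491461956	0.99757
O	16.99913170	0.00038
O	17.99916107	0.00205
S	31.97207100	0.9499
S	32.97145876	0.0075
S	33.96786690	0.0425
S	35.96708076	0.0001
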