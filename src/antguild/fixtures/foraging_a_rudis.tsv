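# Seasonal foraging effort of Aphaenogaster rudis.  Synthetic digitized
# approximation of the published seasonal foraging figure: fractions of
# maximal effort on the first day of each month; foraging peaks in
# mid-summer and is negligible in winter.
# day_of_year	foraging_fraction
0	0.00
31	0.00
59	0.05
90	0.30
120	0.60
151	0.90
181	1.00
212	0.95
243	0.70
273	0.35
304	0.10
334	0.00
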