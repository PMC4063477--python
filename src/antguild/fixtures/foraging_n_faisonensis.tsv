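# Seasonal foraging effort of Nylanderia faisonensis.  Synthetic digitized
# approximation of the published seasonal foraging figure: fractions of
# maximal effort on the first day of each month.  Foraging peaks in
# mid-summer and stays intense from July through October, with a small
# residual winter activity (the species is occasionally active even in
# January, though not intensely).
# day_of_year	foraging_fraction
0	0.05
31	0.02
59	0.05
90	0.15
120	0.40
151	0.70
181	1.00
212	0.95
243	0.85
273	0.80
304	0.30
334	0.10
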