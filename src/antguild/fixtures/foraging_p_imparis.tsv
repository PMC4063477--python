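# Seasonal foraging effort of Prenolepis imparis (the "winter ant") at a
# mid-Atlantic deciduous-forest site.  Synthetic digitized approximation of
# the published seasonal foraging figure: values are fractions of maximal
# effort read for the first day of each month; the species forages most
# intensely in fall and spring with a pronounced drop over the summer.
# day_of_year	foraging_fraction
0	0.40
31	0.55
59	0.90
90	1.00
120	0.50
151	0.10
181	0.02
212	0.02
243	0.10
273	0.45
304	0.80
334	0.50
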