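# Seasonal food production (understory arthropod abundance as a proxy for
# food availability) at a mid-Atlantic deciduous-forest site.  Synthetic
# digitized approximation of the published seasonal abundance figure on the
# 17 measured time points across the year; fractions of the seasonal
# maximum.  Availability is moderate in early spring and late fall, peaks
# in mid-summer, and bottoms out in mid-winter.
# day_of_year	availability_fraction
0	0.15
21	0.15
43	0.25
64	0.45
86	0.65
107	0.80
129	0.95
150	1.00
172	0.90
193	0.80
215	0.70
236	0.60
258	0.55
279	0.50
300	0.45
322	0.30
343	0.20
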