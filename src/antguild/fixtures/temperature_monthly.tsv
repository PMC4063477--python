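# Baseline monthly mean air temperatures (deg C), Jan..Dec.  Synthetic
# stand-in with a mid-Atlantic (Chesapeake Bay) seasonal shape for the
# site's historical record; user-replaceable.
# month	mean_temp_c
1	1.0
2	2.0
3	7.0
4	13.0
5	18.0
6	23.0
7	26.0
8	25.0
9	21.0
10	15.0
11	9.0
12	3.0
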