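# Hairpin loop initiation free energies at 37 C (kcal/mol) by loop size (nt).
# Sizes between table entries are linearly interpolated; sizes beyond the
# largest entry are extrapolated logarithmically (Jacobson-Stockmayer).
size	dg37
3	3.5
4	3.5
5	3.3
6	4.0
7	4.2
8	4.3
9	4.5
10	4.4
12	4.7
14	5.0
16	5.1
18	5.2
20	5.3
25	5.6
30	5.9
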