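# Serum metabolite reference: 23 metabolites with 1H chemical shifts,
# multiplicities, relative peak weights, baseline relative serum level,
# group effects (direction:fold) for the three pairwise comparisons, and
# the non-overlapping peak(s) used for window quantification.
# Isoleucine and valine methyl shifts are placed at 0.92/0.98 ppm (the
# aliphatic region); listings of these resonances near 9.8-9.9 ppm are
# physically implausible for branched-chain amino acids.
# peaks = center:multiplicity:weight;...   multiplicity in {s,d,t,q,m,bra}
name	peaks	base_level	polyp_vs_control	crc_vs_control	crc_vs_polyp	quant_peaks
Lipid	0.86:bra:1.0	3.0	up:1.07	down:1.19	down:1.15	0.86
Leucine	0.96:t:0.6;1.70:m:0.3;3.73:m:0.1	0.8	up:1.08	down:1.23	down:1.16	0.96
Isoleucine	0.92:t:0.45;1.02:d:0.45;3.73:m:0.1	0.4	none:1.01	up:1.28	none:1.01	1.02
Valine	0.98:d:0.45;1.05:d:0.45;3.61:d:0.1	0.8	down:1.09	down:1.17	down:1.12	1.05
3-Hydroxybutyrate	1.20:d:0.6;2.28:q:0.15;2.40:q:0.15;4.15:m:0.1	0.5	none:1.01	up:1.59	none:1.08	1.20
Lactate	1.33:d:0.75;4.12:q:0.25	2.5	up:1.51	up:1.48	none:1.06	1.33
Alanine	1.48:d:0.75;3.78:q:0.25	1.0	down:1.12	down:1.17	down:1.18	1.48
Acetate	1.92:s:1.0	0.6	up:1.21	up:1.18	none:1.02	1.92
Glutamate	2.08:m:0.5;2.34:m:0.5	0.8	up:1.41	up:1.20	up:1.18	2.08
Glutamine	2.13:m:0.5;2.45:m:0.5	1.2	down:1.19	down:1.18	down:1.19	2.45
Succinate	2.37:s:1.0	0.3	down:1.12	down:1.23	none:1.13	2.37
Citrate	2.54:d:0.5;2.66:d:0.5	0.4	none:1.01	down:1.21	down:1.17	2.66
Aspartate	2.87:m:0.5;2.94:m:0.5	0.3	down:1.40	down:1.62	none:1.09	2.94
Choline	3.20:s:1.0	0.7	up:1.23	up:1.20	none:1.02	3.20
Proline	3.36:m:1.0	0.5	none:1.03	down:1.20	down:1.26	3.36
Glycine	3.57:s:1.0	0.9	up:1.19	up:1.46	none:1.04	3.57
Glucose	3.24:q:0.17;3.48:t:0.17;3.90:q:0.17;3.54:t:0.17;3.71:t:0.16;3.83:t:0.16	5.0	down:1.25	up:1.53	up:1.31	3.90
Serine	3.84:m:0.5;3.96:m:0.5	0.6	up:1.32	up:1.18	up:1.23	3.96
Tyrosine	6.90:d:0.5;7.20:d:0.5	0.3	none:1.01	down:1.19	down:1.22	6.90
NAc	2.03:s:1.0	1.5	down:1.27	none:1.01	up:1.21	2.03
PUFA	2.80:bra:1.0	0.8	up:1.18	none:1.04	down:1.37	2.80
Glycerol	3.61:m:0.5;3.65:m:0.5	0.6	down:1.32	none:1.07	none:1.05	3.65
Lysine	1.45:m:0.2;1.71:m:0.2;1.89:m:0.2;3.02:t:0.2;3.75:t:0.2	0.7	none:1.02	none:1.03	up:1.26	3.02
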