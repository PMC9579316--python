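# Published detection-rate report for 2-5 person mixtures typed on a
# 45-locus MH panel: allele counts partitioned into major-contributor
# alleles and minor-unique alleles, with percentage detection rates.
n_contributors	ratio	max_alleles	detected_alleles	detection_rate	major_alleles	major_detected	major_rate	minor_alleles	minor_detected	minor_rate
2	9:1	117	117	100.00	78	78	100.00	39	39	100.00
2	19:1	117	115	98.29	78	78	100.00	39	37	94.87
2	49:1	117	109	93.16	78	78	100.00	39	31	79.49
2	99:1	117	105	89.74	78	78	100.00	39	27	69.23
2	199:1	117	101	86.32	78	78	100.00	39	23	58.97
3	7:2:1	135	135	100.00	73	73	100.00	62	62	100.00
3	17:2:1	135	132	97.78	73	73	100.00	62	59	95.16
3	47:2:1	135	125	92.59	73	73	100.00	62	52	83.87
3	97:2:1	135	120	88.89	73	73	100.00	62	47	75.81
3	197:2:1	135	111	82.22	73	73	100.00	62	38	61.29
4	5:2:2:1	163	163	100.00	79	79	100.00	84	84	100.00
4	13:4:2:1	163	162	99.39	79	79	100.00	84	83	98.81
4	43:4:2:1	163	160	98.16	79	79	100.00	84	81	96.43
4	93:4:2:1	163	159	97.55	79	79	100.00	84	80	95.24
4	193:4:2:1	163	142	87.12	79	79	100.00	84	63	75.00
5	3:2:2:2:1	173	173	100.00	82	82	100.00	91	91	100.00
5	13:2:2:2:1	173	173	100.00	82	82	100.00	91	91	100.00
5	35:8:4:2:1	173	170	98.27	82	82	100.00	91	88	96.70
5	85:8:4:2:1	173	165	95.38	82	82	100.00	91	83	91.21
5	185:8:4:2:1	173	159	91.91	82	82	100.00	91	77	84.62
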