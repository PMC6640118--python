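# Species-level classification accuracy (%) of paired-end V-region targets on
# mock communities: five replicate datasets of 10,000 16S genes were drawn from
# each of five random 50-genus gene pools; each cell is the accuracy averaged
# over the five replicates of one pool.  Contiguous (merged-read) targets are
# marked with a trailing asterisk.  reported_average is the published rounded
# mean of the five pool columns.
combination	pool1	pool2	pool3	pool4	pool5	reported_average
V1+V4	77.29	79.47	72.79	75.90	80.48	77.19
V1+V3	74.69	78.16	77.52	74.76	80.08	77.04
V1+V8	76.03	77.96	73.24	75.72	79.32	76.46
V1+V7	77.20	78.33	70.37	77.34	78.60	76.37
V1+V6	72.46	77.34	69.73	78.25	76.90	74.94
V1+V5	70.89	74.24	69.16	73.37	76.40	72.81
V1+V9	71.74	71.41	71.33	73.95	75.57	72.80
V2+V4	69.07	75.07	72.76	70.99	73.55	72.29
V2+V8	68.26	74.60	73.33	70.66	73.27	72.02
V2+V6	66.84	74.54	72.60	72.19	72.67	71.77
V2+V7	68.34	72.76	72.73	71.17	71.30	71.26
V2V3*	61.53	71.52	72.03	66.31	73.92	69.06
V2+V9	65.03	68.85	71.60	66.32	71.81	68.72
V1V2*	64.20	70.29	66.81	65.44	72.40	67.83
V3+V8	68.47	61.80	69.66	66.59	67.82	66.87
V3+V7	68.41	61.60	71.05	66.80	65.93	66.76
V2+V5	61.38	68.19	68.42	65.36	69.34	66.54
V3+V6	63.26	59.91	68.53	67.04	65.15	64.78
V3+V9	63.63	55.85	67.20	65.94	63.83	63.29
V3+V5	60.94	56.74	65.79	62.91	62.49	61.77
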