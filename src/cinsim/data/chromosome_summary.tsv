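# Per-chromosome annotation summary used to rebuild the default fitness landscape.
# length_mb: GRCh38 sequence length (Mb). coding_genes: approximate protein-coding
# gene count (Ensembl-style consensus). centromere_mb: approximate active
# alpha-satellite array size (Mb), rounded literature estimates.
chrom	length_mb	coding_genes	centromere_mb
1	248.96	2058	2.9
2	242.19	1309	1.8
3	198.30	1078	2.0
4	190.21	752	2.4
5	181.54	876	2.2
6	170.81	1048	2.1
7	159.35	989	2.6
8	145.14	677	2.2
9	138.39	786	1.7
10	133.80	733	1.6
11	135.09	1298	2.8
12	133.28	1034	1.8
13	114.36	327	1.9
14	107.04	830	1.4
15	101.99	613	1.7
16	90.34	873	1.6
17	83.26	1197	2.3
18	80.37	270	2.0
19	58.62	1472	1.6
20	64.44	544	1.7
21	46.71	234	0.8
22	50.82	488	1.2
X	156.04	842	3.1
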