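# Default per-chromosome fitness landscape (synthetic reconstruction).
# Built by scripts/build_landscape.py from the vendored gene lists and
# chromosome_summary.tsv; all five tracks are max-normalized densities.
# Version: 1
chrom	alpha	beta	gamma	s_gd	s_cen
1	0.549406	0.267674	0.176595	0.329195	0.935484
2	0.242041	0.206367	0.211786	0.215239	0.580645
3	0.197075	0.336056	0.22171	0.216488	0.645161
4	0.308186	0.437937	0.192616	0.157443	0.774194
5	0.322904	0.367082	0.201815	0.192163	0.709677
6	0.343188	0.097535	0.085797	0.244335	0.677419
7	0.122623	0.313649	0.367869	0.247162	0.83871
8	0.201943	0.114786	0.201943	0.185755	0.709677
9	0.211793	0.842691	0.317689	0.226181	0.548387
10	0.365097	0.498057	0.273823	0.218165	0.516129
11	0.940188	0.739951	0.216966	0.382639	0.903226
12	0.439826	1.0	0.329869	0.308954	0.580645
13	0.256296	0.291361	0.128148	0.113871	0.612903
14	0.091274	0.155643	0.136911	0.308795	0.451613
15	0.0	0.0	0.143691	0.239354	0.548387
16	0.648882	0.553243	0.324441	0.384833	0.516129
17	0.586716	0.600288	0.70406	0.572527	0.741935
18	0.121563	0.207291	0.182344	0.133785	0.645161
19	1.0	0.568407	1.0	1.0	0.516129
20	0.303228	0.258535	0.227421	0.336187	0.548387
21	0.209163	0.356669	0.313744	0.199501	0.258065
22	0.768989	0.655647	0.144185	0.382405	0.387097
X	0.313061	0.320302	0.140877	0.214889	1.0
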