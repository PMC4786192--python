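method	cutoff	tp	fp	fn	tn	mcc	accy	prec	sensy	mcc_corr
SVB	4	7	54	938	6504	-0.0031	0.866	0.115	0.007	0.0032
SVB	6	22	156	837	6488	0.0045	0.862	0.124	0.026	0.0248
SVB	8	34	279	713	6477	0.0063	0.859	0.109	0.046	0.0441
SVB	10	62	494	498	6449	0.0397	0.851	0.112	0.111	0.1073
SVB	12	107	796	197	6403	0.1463	0.839	0.118	0.352	0.2589
SVB	14	146	1123	130	6104	0.1876	0.794	0.115	0.529	0.3583
SVB	16	198	1514	521	5270	0.0366	0.676	0.116	0.275	0.2831
SVB	18	256	1870	877	4500	-0.0537	0.566	0.120	0.226	0.2715
SVB	20	310	2253	1260	3680	-0.1564	0.449	0.121	0.197	0.2673
P2P	4	7	61	23	7412	0.1499	0.987	0.103	0.233	0.1050
P2P	6	7	162	78	7256	0.0432	0.966	0.041	0.082	0.0635
P2P	8	9	286	202	7006	0.0029	0.933	0.031	0.043	0.0407
P2P	10	13	501	417	6572	-0.0374	0.874	0.025	0.030	0.0302
P2P	12	23	802	718	5960	-0.0835	0.791	0.028	0.031	0.0301
P2P	14	32	1130	1046	5295	-0.1417	0.701	0.028	0.030	0.0290
P2P	16	38	1520	1436	4509	-0.2217	0.596	0.024	0.026	0.0248
P2P	18	43	1876	1792	3792	-0.3030	0.500	0.022	0.023	0.0222
P2P	20	47	2260	2176	3020	-0.4026	0.396	0.020	0.021	0.0211
KOL	4	13	47	331	7112	0.0733	0.946	0.217	0.038	0.0796
KOL	6	35	148	229	7091	0.1339	0.940	0.191	0.133	0.1542
KOL	8	58	272	106	7067	0.2258	0.934	0.176	0.354	0.2636
KOL	10	102	487	109	6805	0.2561	0.893	0.173	0.483	0.3237
KOL	12	153	788	410	6152	0.1259	0.800	0.163	0.272	0.2385
KOL	14	200	1116	738	5449	0.0376	0.700	0.152	0.213	0.2083
KOL	16	266	1506	1128	4603	-0.0510	0.578	0.150	0.191	0.1955
KOL	18	304	1862	1484	3853	-0.1465	0.473	0.140	0.170	0.1787
KOL	20	340	2246	1868	3049	-0.2591	0.361	0.131	0.154	0.1646
VRN	4	10	61	374	7058	0.0398	0.939	0.141	0.026	0.0461
VRN	6	35	162	272	7034	0.1134	0.933	0.178	0.114	0.1337
VRN	8	66	286	149	7002	0.2112	0.924	0.188	0.307	0.2490
VRN	10	120	501	66	6816	0.3254	0.892	0.193	0.645	0.4200
VRN	12	187	802	367	6147	0.1717	0.794	0.189	0.338	0.2843
VRN	14	245	1130	695	5433	0.0757	0.691	0.178	0.261	0.2464
VRN	16	306	1520	1085	4592	-0.0260	0.571	0.168	0.220	0.2205
VRN	18	350	1876	1441	3836	-0.1241	0.465	0.157	0.195	0.2011
VRN	20	387	2260	1825	3031	-0.2406	0.352	0.146	0.175	0.1921
CMA	4	0	61	88	7354	-0.0099	0.980	0.000	0.000	-0.0036
CMA	6	3	162	13	7325	0.0522	0.976	0.018	0.188	0.0725
CMA	8	5	286	137	7075	-0.0026	0.942	0.017	0.035	0.0352
CMA	10	7	501	352	6643	-0.0430	0.884	0.014	0.019	0.0246
CMA	12	8	802	653	6040	-0.0960	0.804	0.010	0.012	0.0166
CMA	14	9	1130	981	5383	-0.1551	0.716	0.008	0.009	0.0156
CMA	16	15	1520	1371	4597	-0.2286	0.611	0.010	0.011	0.0179
CMA	18	24	1876	1727	3876	-0.3039	0.513	0.013	0.014	0.0382
CMA	20	28	2260	2111	3104	-0.4003	0.410	0.012	0.013	0.0234
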