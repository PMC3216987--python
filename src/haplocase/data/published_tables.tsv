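# Case-control haplogroup rows of the three published comparisons.
# comparison: cases_vs_controls; a = cases carrying the class, c = controls carrying it.
# p/or/ci columns are the values printed in the source tables (3 decimals; p as printed).
# note: ok = reproducible from counts; zero_cell = single-zero-cell fallback row;
#       known_inconsistent = printed OR/CI not derivable from the printed counts.
comparison	haplogroup	n_case	n_control	a	c	p_printed	or_printed	ci_low_printed	ci_high_printed	note
suspected_vs_han	A	843	1689	31	92	0.064	0.663	0.437	1.004	ok
suspected_vs_han	B4	843	1689	126	196	0.021	1.339	1.052	1.703	ok
suspected_vs_han	B5	843	1689	54	94	0.448	1.161	0.822	1.640	ok
suspected_vs_han	C	843	1689	35	51	0.172	1.391	0.897	2.157	ok
suspected_vs_han	D4	843	1689	115	252	0.423	0.901	0.710	1.143	ok
suspected_vs_han	D5	843	1689	32	88	0.139	0.718	0.475	1.085	ok
suspected_vs_han	R9	843	1689	164	305	0.394	1.413	0.804	2.483	known_inconsistent
suspected_vs_han	F	843	1689	143	274	0.677	1.055	0.845	1.317	ok
suspected_vs_han	F1	843	1689	99	193	0.229	1.175	0.903	1.530	known_inconsistent
suspected_vs_han	F1a	843	1689	71	132	0.281	1.165	0.882	1.541	known_inconsistent
suspected_vs_han	F2	843	1689	17	48	0.216	1.421	0.812	2.487	known_inconsistent
suspected_vs_han	F2a	843	1689	16	22	0.246	1.466	0.766	2.806	ok
suspected_vs_han	F3	843	1689	12	15	0.216	1.612	0.751	3.458	ok
suspected_vs_han	F3a	843	1689	12	13	0.117	1.862	0.846	4.098	ok
suspected_vs_han	F4	843	1689	7	8	0.270	1.759	0.636	4.868	ok
suspected_vs_han	G	843	1689	31	71	0.598	0.870	0.566	1.338	ok
suspected_vs_han	M10	843	1689	14	35	0.579	0.798	0.427	1.492	ok
suspected_vs_han	M12	843	1689	8	4	0.031	4.036	1.212	13.441	ok
suspected_vs_han	M7b	843	1689	59	119	1.000	0.993	0.718	1.372	ok
suspected_vs_han	M7c	843	1689	32	54	0.504	1.195	0.765	1.865	ok
suspected_vs_han	M8a	843	1689	27	63	0.575	0.854	0.540	1.351	ok
suspected_vs_han	M9a	843	1689	11	29	0.539	0.757	0.376	1.522	ok
suspected_vs_han	N9a	843	1689	33	62	0.847	1.069	0.695	1.645	ok
suspected_vs_han	R11	843	1689	5	10	1.000	1.002	0.341	2.940	ok
suspected_vs_han	Y	843	1689	7	16	0.944	0.876	0.359	2.136	ok
suspected_vs_han	Z	843	1689	21	50	0.585	0.837	0.500	1.404	ok
lhon304_vs_suspected	A	304	843	6	31	0.150	0.527	0.218	1.277	ok
lhon304_vs_suspected	B4	304	843	43	126	0.735	0.938	0.645	1.363	ok
lhon304_vs_suspected	B5	304	843	21	54	0.761	1.084	0.643	1.827	ok
lhon304_vs_suspected	C	304	843	14	35	0.738	1.114	0.591	2.101	ok
lhon304_vs_suspected	D4	304	843	58	115	0.023	1.493	1.055	2.112	ok
lhon304_vs_suspected	D5	304	843	13	32	0.712	1.132	0.586	2.187	ok
lhon304_vs_suspected	R9	304	843	4	164	5.190e-19	0.055	0.020	0.150	ok
lhon304_vs_suspected	F	304	843	3	143	4.319e-17	0.049	0.015	0.154	ok
lhon304_vs_suspected	F1	304	843	2	99	1.003e-11	0.050	0.012	0.203	ok
lhon304_vs_suspected	F1a	304	843	1	71	6.614e-9	0.036	0.005	0.259	ok
lhon304_vs_suspected	F2	304	843	0	17	9.725e-3	0.731	0.706	0.757	zero_cell
lhon304_vs_suspected	F3	304	843	1	12	0.203	0.229	0.030	1.765	ok
lhon304_vs_suspected	F3a	304	843	1	12	0.203	0.229	0.030	1.765	ok
lhon304_vs_suspected	F4	304	843	0	7	0.200	0.733	0.708	0.759	zero_cell
lhon304_vs_suspected	G	304	843	14	31	0.475	1.265	0.663	2.411	ok
lhon304_vs_suspected	M10	304	843	13	14	0.010	2.645	1.229	5.694	ok
lhon304_vs_suspected	M12	304	843	0	8	0.119	0.733	0.708	0.759	zero_cell
lhon304_vs_suspected	M7b	304	843	42	59	3.233e-4	2.130	1.400	3.241	ok
lhon304_vs_suspected	M7c	304	843	15	32	0.391	1.315	0.702	2.465	rounding_ulp
lhon304_vs_suspected	M8a	304	843	11	27	0.729	1.135	0.556	2.316	ok
lhon304_vs_suspected	M9a	304	843	9	11	0.059	2.308	0.947	5.624	ok
lhon304_vs_suspected	N9a	304	843	12	33	0.980	1.009	0.514	1.979	ok
lhon304_vs_suspected	R11	304	843	0	5	0.333	0.734	0.709	0.760	zero_cell
lhon304_vs_suspected	Y	304	843	5	7	0.232	1.997	0.629	6.340	ok
lhon304_vs_suspected	Z	304	843	8	21	0.894	1.058	0.464	2.414	ok
lhon304_vs_han	A	304	1689	6	92	0.010	0.350	0.152	0.806	ok
lhon304_vs_han	B4	304	1689	43	196	0.210	1.255	0.880	1.790	ok
lhon304_vs_han	B5	304	1689	21	94	0.355	1.259	0.772	2.055	ok
lhon304_vs_han	C	304	1689	14	51	0.152	1.551	0.847	2.838	ok
lhon304_vs_han	D4	304	1689	58	252	0.065	1.344	0.980	1.844	ok
lhon304_vs_han	D5	304	1689	13	88	0.494	0.813	0.448	1.474	ok
lhon304_vs_han	R9	304	1689	4	304	7.621e-19	0.061	0.022	0.164	ok
lhon304_vs_han	F	304	1689	3	274	1.461e-17	0.051	0.016	0.162	ok
lhon304_vs_han	F1	304	1689	2	193	2.822e-12	0.051	0.013	0.208	ok
lhon304_vs_han	F1a	304	1689	1	132	5.356e-9	0.039	0.005	0.280	rounding_ulp
lhon304_vs_han	F2	304	1689	0	48	7.125e-4	0.844	0.828	0.860	zero_cell
lhon304_vs_han	F3	304	1689	1	15	0.492	0.368	0.049	2.799	rounding_ulp
lhon304_vs_han	F3a	304	1689	1	13	0.708	0.425	0.055	3.265	ok
lhon304_vs_han	F4	304	1689	0	8	0.616	0.847	0.831	0.863	zero_cell
lhon304_vs_han	G	304	1689	14	71	0.750	1.100	0.612	1.978	ok
lhon304_vs_han	M10	304	1689	13	35	0.021	2.111	1.104	4.039	ok
lhon304_vs_han	M12	304	1689	0	4	1.000	0.847	0.831	0.863	zero_cell
lhon304_vs_han	M7b	304	1689	42	119	6.669e-5	2.115	1.453	3.078	ok
lhon304_vs_han	M7c	304	1689	15	54	0.127	1.572	0.875	2.822	ok
lhon304_vs_han	M8a	304	1689	11	63	0.925	0.969	0.505	1.861	ok
lhon304_vs_han	M9a	304	1689	9	29	0.144	1.746	0.818	3.727	ok
lhon304_vs_han	N9a	304	1689	12	62	0.814	1.078	0.574	2.026	ok
lhon304_vs_han	R11	304	1689	0	10	0.376	0.847	0.831	0.863	zero_cell
lhon304_vs_han	Y	304	1689	5	16	0.273	1.749	0.636	4.809	ok
lhon304_vs_han	Z	304	1689	8	50	0.754	0.886	0.416	1.888	ok
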