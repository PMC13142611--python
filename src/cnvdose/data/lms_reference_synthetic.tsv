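trait	sex	age	L	M	S
height	M	2.0	1.0	86.0	0.03801
height	M	2.5	1.0	90.45	0.03801
height	M	3.0	1.0	94.799	0.03802
height	M	3.5	1.0	99.047	0.03804
height	M	4.0	1.0	103.194	0.03807
height	M	4.5	1.0	107.238	0.03811
height	M	5.0	1.0	111.179	0.03817
height	M	5.5	1.0	115.016	0.03826
height	M	6.0	1.0	118.749	0.03839
height	M	6.5	1.0	122.377	0.03857
height	M	7.0	1.0	125.899	0.03881
height	M	7.5	1.0	129.314	0.03912
height	M	8.0	1.0	132.621	0.0395
height	M	8.5	1.0	135.82	0.03995
height	M	9.0	1.0	138.91	0.04047
height	M	9.5	1.0	141.889	0.04104
height	M	10.0	1.0	144.757	0.04164
height	M	10.5	1.0	147.512	0.04224
height	M	11.0	1.0	150.154	0.0428
height	M	11.5	1.0	152.681	0.04329
height	M	12.0	1.0	155.092	0.04368
height	M	12.5	1.0	157.385	0.04392
height	M	13.0	1.0	159.559	0.044
height	M	13.5	1.0	161.612	0.04392
height	M	14.0	1.0	163.543	0.04368
height	M	14.5	1.0	165.349	0.04329
height	M	15.0	1.0	167.028	0.0428
height	M	15.5	1.0	168.578	0.04224
height	M	16.0	1.0	169.996	0.04164
height	M	16.5	1.0	171.279	0.04104
height	M	17.0	1.0	172.423	0.04047
height	M	17.5	1.0	173.423	0.03995
height	M	18.0	1.0	174.276	0.0395
height	M	18.5	1.0	174.973	0.03912
height	M	19.0	1.0	175.505	0.03881
height	M	19.5	1.0	175.858	0.03857
height	M	20.0	1.0	176.0	0.03839
bmi	M	2.0	-1.56	16.008	0.088
bmi	M	2.5	-1.55	15.888	0.09
bmi	M	3.0	-1.54	15.754	0.092
bmi	M	3.5	-1.53	15.621	0.094
bmi	M	4.0	-1.52	15.506	0.096
bmi	M	4.5	-1.51	15.428	0.098
bmi	M	5.0	-1.5	15.4	0.1
bmi	M	5.5	-1.49	15.618	0.102
bmi	M	6.0	-1.48	15.886	0.104
bmi	M	6.5	-1.47	16.191	0.106
bmi	M	7.0	-1.46	16.514	0.108
bmi	M	7.5	-1.45	16.838	0.11
bmi	M	8.0	-1.44	17.148	0.112
bmi	M	8.5	-1.43	17.435	0.114
bmi	M	9.0	-1.42	17.698	0.116
bmi	M	9.5	-1.41	17.938	0.118
bmi	M	10.0	-1.4	18.16	0.12
bmi	M	10.5	-1.39	18.369	0.122
bmi	M	11.0	-1.38	18.57	0.124
bmi	M	11.5	-1.37	18.765	0.126
bmi	M	12.0	-1.36	18.958	0.128
bmi	M	12.5	-1.35	19.149	0.13
bmi	M	13.0	-1.34	19.34	0.132
bmi	M	13.5	-1.33	19.53	0.134
bmi	M	14.0	-1.32	19.72	0.136
bmi	M	14.5	-1.31	19.91	0.138
bmi	M	15.0	-1.3	20.1	0.14
bmi	M	15.5	-1.29	20.29	0.142
bmi	M	16.0	-1.28	20.48	0.144
bmi	M	16.5	-1.27	20.67	0.146
bmi	M	17.0	-1.26	20.86	0.148
bmi	M	17.5	-1.25	21.05	0.15
bmi	M	18.0	-1.24	21.24	0.152
bmi	M	18.5	-1.23	21.43	0.154
bmi	M	19.0	-1.22	21.62	0.156
bmi	M	19.5	-1.21	21.81	0.158
bmi	M	20.0	-1.2	22.0	0.16
height	F	2.0	1.0	85.0	0.03801
height	F	2.5	1.0	88.857	0.03801
height	F	3.0	1.0	92.626	0.03802
height	F	3.5	1.0	96.308	0.03804
height	F	4.0	1.0	99.901	0.03807
height	F	4.5	1.0	103.406	0.03811
height	F	5.0	1.0	106.822	0.03817
height	F	5.5	1.0	110.147	0.03826
height	F	6.0	1.0	113.383	0.03839
height	F	6.5	1.0	116.527	0.03857
height	F	7.0	1.0	119.579	0.03881
height	F	7.5	1.0	122.538	0.03912
height	F	8.0	1.0	125.405	0.0395
height	F	8.5	1.0	128.177	0.03995
height	F	9.0	1.0	130.855	0.04047
height	F	9.5	1.0	133.437	0.04104
height	F	10.0	1.0	135.923	0.04164
height	F	10.5	1.0	138.311	0.04224
height	F	11.0	1.0	140.6	0.0428
height	F	11.5	1.0	142.79	0.04329
height	F	12.0	1.0	144.88	0.04368
height	F	12.5	1.0	146.867	0.04392
height	F	13.0	1.0	148.751	0.044
height	F	13.5	1.0	150.531	0.04392
height	F	14.0	1.0	152.204	0.04368
height	F	14.5	1.0	153.769	0.04329
height	F	15.0	1.0	155.224	0.0428
height	F	15.5	1.0	156.567	0.04224
height	F	16.0	1.0	157.796	0.04164
height	F	16.5	1.0	158.908	0.04104
height	F	17.0	1.0	159.9	0.04047
height	F	17.5	1.0	160.767	0.03995
height	F	18.0	1.0	161.506	0.0395
height	F	18.5	1.0	162.11	0.03912
height	F	19.0	1.0	162.571	0.03881
height	F	19.5	1.0	162.877	0.03857
height	F	20.0	1.0	163.0	0.03839
bmi	F	2.0	-1.56	16.008	0.088
bmi	F	2.5	-1.55	15.888	0.09
bmi	F	3.0	-1.54	15.754	0.092
bmi	F	3.5	-1.53	15.621	0.094
bmi	F	4.0	-1.52	15.506	0.096
bmi	F	4.5	-1.51	15.428	0.098
bmi	F	5.0	-1.5	15.4	0.1
bmi	F	5.5	-1.49	15.618	0.102
bmi	F	6.0	-1.48	15.886	0.104
bmi	F	6.5	-1.47	16.191	0.106
bmi	F	7.0	-1.46	16.514	0.108
bmi	F	7.5	-1.45	16.838	0.11
bmi	F	8.0	-1.44	17.148	0.112
bmi	F	8.5	-1.43	17.435	0.114
bmi	F	9.0	-1.42	17.698	0.116
bmi	F	9.5	-1.41	17.938	0.118
bmi	F	10.0	-1.4	18.16	0.12
bmi	F	10.5	-1.39	18.369	0.122
bmi	F	11.0	-1.38	18.57	0.124
bmi	F	11.5	-1.37	18.765	0.126
bmi	F	12.0	-1.36	18.958	0.128
bmi	F	12.5	-1.35	19.149	0.13
bmi	F	13.0	-1.34	19.34	0.132
bmi	F	13.5	-1.33	19.53	0.134
bmi	F	14.0	-1.32	19.72	0.136
bmi	F	14.5	-1.31	19.91	0.138
bmi	F	15.0	-1.3	20.1	0.14
bmi	F	15.5	-1.29	20.29	0.142
bmi	F	16.0	-1.28	20.48	0.144
bmi	F	16.5	-1.27	20.67	0.146
bmi	F	17.0	-1.26	20.86	0.148
bmi	F	17.5	-1.25	21.05	0.15
bmi	F	18.0	-1.24	21.24	0.152
bmi	F	18.5	-1.23	21.43	0.154
bmi	F	19.0	-1.22	21.62	0.156
bmi	F	19.5	-1.21	21.81	0.158
bmi	F	20.0	-1.2	22.0	0.16
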