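sample_id	fusion	gene5	gene3	orf	tk	rtk_side	in_db	db_literature	downstream	expr5	expr3	n_reads	label
AL-98	BCR-ABL1	BCR	ABL1	yes	yes	3'	yes	no	yes	1.02	0.47	1	confirmed
FS-1	CCDC6-RET	CCDC6	RET	yes	yes	3'	yes	no	yes	0.4	0.35	3	confirmed
LuC-46	SLC34A2-ROS1 variant 1	SLC34A2	ROS1	yes	yes	3'	yes	no	yes	24.53	5.29	1	confirmed
LuC-46	SLC34A2-ROS1 variant 2	SLC34A2	ROS1	yes	yes	3'	yes	no	yes	23.29	6.09	5	confirmed
LuC-46	SLC34A2-ROS1 variant 3	SLC34A2	ROS1	yes	yes	3'	yes	no	yes	23.29	5.87	4	confirmed
LuC-46	SLC34A2-ROS1 variant 4	SLC34A2	ROS1	no	yes	3'	yes	no	yes	23.29	5.93	1	confirmed
OC-11	FGFR2-LGSN	FGFR2	LGSN	yes	yes	5'	no	yes	ND	0.72	0.43	6	confirmed
OC-11	RPS24-FGFR2	RPS24	FGFR2	yes	no	3'	no	no	no	5.74	0.29	5	confirmed
BC-105	FBXL20-ERBB2	FBXL20	ERBB2	no	yes	3'	yes	no	yes	1.28	11.77	18	confirmed
BC-105	ATP2B1-ERBB2	ATP2B1	ERBB2	yes	yes	3'	no	no	no	0.41	12.41	8	confirmed
GC-30	ABL1-ALDH1A2	ABL1	ALDH1A2	yes	no	5'	no	no	ND	0.04	0.43	1	non_confirmed
LuC-71	NTRK2-AL157886.1	NTRK2	AL157886.1	no	no	5'	no	no	ND	NA	NA	1	non_confirmed
LuC-11	KIF27-NTRK2	KIF27	NTRK2	yes	yes	3'	no	no	no	0.02	0.67	1	non_confirmed
LuC-19	NTRK2-USP47	NTRK2	USP47	no	no	5'	no	no	ND	0.83	0.24	1	non_confirmed
LuC-81	ETNK1-NTRK2	ETNK1	NTRK2	no	no	5'	no	no	ND	0.22	6.36	1	non_confirmed
XC-1	FGFR2-NFYC	FGFR2	NFYC	no	no	5'	no	no	ND	0.33	0.31	1	non_confirmed
OC-15	ABL1-FNIP2	ABL1	FNIP2	yes	no	5'	no	no	ND	0.45	0.8	1	non_confirmed
AL-44	FGFR1-AZIN1	FGFR1	AZIN1	no	no	5'	no	no	ND	0.15	0.6	1	non_confirmed
AL-7	RET-GART	RET	GART	no	no	5'	no	no	ND	0.016	0.48	1	non_confirmed
J1	RBM18-ABL1	RBM18	ABL1	no	no	3'	no	no	no	1.94	1.9	1	non_confirmed
A549	FGFR1-BRF1	FGFR1	BRF1	yes	no	5'	no	no	ND	1.21	0.52	1	non_confirmed
SkC-1	ABL1-CD59	ABL1	CD59	no	no	5'	no	no	ND	0.05	3.58	1	non_confirmed
BC-59	FGFR1-REPS2	FGFR1	REPS2	no	no	5'	no	no	ND	0.55	1.5	1	non_confirmed
EpS-1	HMBOX1-FGFR1	HMBOX1	FGFR1	no	no	3'	no	no	no	0.34	5.89	1	non_confirmed
PC-24	DOCK1-FGFR2	DOCK1	FGFR2	yes	yes	3'	no	no	no	0.12	0.023	1	non_confirmed
TC-123	NTRK2-MLPH	NTRK2	MLPH	no	no	5'	no	no	ND	0.97	0.22	1	unexplored
N-63	CNTNAP3-NTRK2	CNTNAP3	NTRK2	no	no	3'	no	no	yes	0.88	0.24	8	unexplored
RAIR-4	NCOA4-RET	NCOA4	RET	yes	yes	3'	yes	no	yes	0.69	0.11	1	unexplored
TC-32	NTRK2-IARS1	NTRK2	IARS1	yes	no	5'	no	no	ND	2.55	0.74	1	unexplored
TC-12	ARHGAP12-ALK	ARHGAP12	ALK	no	yes	3'	no	no	yes	0.46	0.02	1	unexplored
BT-24	NTRK2-ADAM32	NTRK2	ADAM32	yes	yes	5'	no	no	ND	0.23	0.006	1	unexplored
BC-47	FGFR2-RET	FGFR2	RET	yes	yes	both	no	no	no	0.06	1.36	1	unexplored
FFPE_4-2	ZNF135-FGFR2	ZNF135	FGFR2	yes	yes	3'	no	no	no	0.06	0.46	1	unexplored
AL-84	AGRN-FGFR3	AGRN	FGFR3	no	yes	3'	no	no	yes	0.82	0.17	1	unexplored
FFPE-5	AC016907.2-ALK	AC016907.2	ALK	no	yes	3'	no	no	no	NA	NA	1	unexplored
INI-1	KIF5C-NTRK3	KIF5C	NTRK3	yes	no	3'	no	no	yes	1.17	0.19	1	unexplored
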