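animal_id	het_parent_sex	rb_count	diploid_n	plate_counts
F001	female	0	40	
F002	female	0	40	
F003	female	0	40	
F004	female	0	40	
F005	female	0	40	
F006	female	0	40	
F007	female	1	39	
F008	female	1	39	
F009	female	1	39	
F010	female	1	39	
F011	female	1	39	
F012	female	1	39	
F013	female	1	39	
F014	female	2	38	
F015	female	2	38	
F016	female	2	38	
F017	female	2	38	
F018	female	2	38	
F019	female	2	38	
F020	female	2	38	
F021	female	2	38	
F022	female	2	38	
F023	female	2	38	
F024	female	2	38	
F025	female	2	38	
F026	female	2	38	
F027	female	2	38	
F028	female	2	38	
F029	female	2	38	
F030	female	2	38	
F031	female	2	38	
F032	female	2	38	
F033	female	2	38	
F034	female	2	38	
F035	female	2	38	
F036	female	3	37	
F037	female	3	37	
F038	female	3	37	
F039	female	3	37	
F040	female	3	37	
F041	female	3	37	
F042	female	3	37	
F043	female	3	37	
F044	female	3	37	
F045	female	3	37	
F046	female	4	36	
F047	female	4	36	
F048	female	4	36	
F049	female	4	36	
F050	female	4	36	
F051	female	4	36	
F052	female	4	36	
F053	female	4	36	
F054	female	4	36	
F055	female	4	36	
F056	female	4	36	
F057	female	4	36	
F058	female	4	36	
F059	female	4	36	
F060	female	4	36	
F061	female	4	36	
F062	female	4	36	
F063	female	4	36	
F064	female	4	36	
F065	female	4	36	
F066	female	5	35	
F067	female	5	35	
F068	female	5	35	
F069	female	5	35	
F070	female	5	35	
F071	female	5	35	
F072	female	5	35	
F073	female	5	35	
F074	female	5	35	
F075	female	5	35	
F076	female	5	35	
F077	female	5	35	
F078	female	5	35	
F079	female	5	35	
F080	female	5	35	
F081	female	6	34	
F082	female	6	34	
F083	female	8	32	
M001	male	0	40	
M002	male	0	40	
M003	male	1	39	
M004	male	2	38	
M005	male	2	38	
M006	male	2	38	
M007	male	2	38	
M008	male	2	38	
M009	male	3	37	
M010	male	3	37	
M011	male	3	37	
M012	male	3	37	
M013	male	3	37	
M014	male	3	37	
M015	male	3	37	
M016	male	3	37	
M017	male	3	37	
M018	male	3	37	
M019	male	3	37	
M020	male	3	37	
M021	male	3	37	
M022	male	3	37	
M023	male	4	36	
M024	male	4	36	
M025	male	4	36	
M026	male	4	36	
M027	male	4	36	
M028	male	4	36	
M029	male	4	36	
M030	male	4	36	
M031	male	4	36	
M032	male	4	36	
M033	male	4	36	
M034	male	4	36	
M035	male	4	36	
M036	male	4	36	
M037	male	5	35	
M038	male	5	35	
M039	male	5	35	
M040	male	5	35	
M041	male	5	35	
M042	male	5	35	
M043	male	5	35	
M044	male	5	35	
M045	male	5	35	
M046	male	5	35	
M047	male	6	34	
M048	male	6	34	
M049	male	6	34	
M050	male	6	34	
M051	male	6	34	
M052	male	7	33	
M053	male	8	32	
M054	male	8	32	
M055	male	8	32	
M056	male	8	32	
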