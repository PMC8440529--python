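patient_id	age	sex	smoking	stage	tumor_size	histology	treatment_after_surgery	dfs_time	dfs_event	os_time	os_event	tnb	egfr_classic
T001	23	male	smoker	I	1.6	P-SCLC	True	2	True	6	True	20	True
T002	34	male	smoker	I	5	P-SCLC	True	3	True	8	True	27	True
T003	41	male	smoker	I	8	P-SCLC	True	4	True	10	True	34	False
T004	45	male	smoker	I	10	P-SCLC	True	5	True	12	True	41	False
T005	48	male	smoker	I	12	P-SCLC	True	6	True	14	True	48	False
T006	50	male	smoker	I	14	P-SCLC	True	12	True	16	True	55	False
T007	52	male	smoker	I	15	P-SCLC	True	13	True	18	True	62	False
T008	54	male	smoker	I	16	P-SCLC	True	14	True	20	True	69	False
T009	55	male	smoker	I	17	P-SCLC	True	15	True	22	True	76	False
T010	56	male	smoker	I	18	P-SCLC	True	16	True	24	True	23	False
T011	57	male	smoker	I	19	P-SCLC	True	22	True	26	True	30	False
T012	58	male	smoker	I	20	P-SCLC	True	23	True	28	True	37	False
T013	59	male	smoker	II	21	P-SCLC	True	24	True	30	True	44	False
T014	60	male	smoker	II	21.5	P-SCLC	True	25	True	32	True	51	False
T015	60	male	smoker	II	22	P-SCLC	True	52	False	60	False	58	False
T016	61	male	smoker	II	22	P-SCLC	True	59	True	63	False	65	False
T017	61	male	smoker	II	22	P-SCLC	True	61	False	66	False	72	False
T018	61	male	smoker	III	22.3	P-SCLC	True	63	False	69	False	79	False
T019	62	male	smoker	III	22.4	P-SCLC	True	65	True	72	False	26	False
T020	62	male	smoker	III	22.5	P-SCLC	True	67	False	75	False	33	False
T021	62	male	smoker	III	22.5	P-SCLC	True	74	False	78	False	40	False
T022	62	male	smoker	III	23	P-SCLC	True	76	True	81	False	47	False
T023	63	male	smoker	III	24	P-SCLC	True	78	False	84	False	54	False
T024	63	male	smoker	III	25	P-SCLC	False	11	False	18	False	61	False
T025	64	male	smoker	III	26	P-SCLC	False	13	True	21	False	68	False
T026	64	male	smoker	III	28	P-SCLC	False	20	False	24	False	75	False
T027	65	male	smoker	III	30	P-SCLC	False	22	False	27	False	22	False
T028	65	male	smoker	III	32	P-SCLC	False	24	True	30	False	29	False
T029	66	male	non-smoker	III	35	P-SCLC	False	26	False	33	False	36	False
T030	67	male	non-smoker	III	38	P-SCLC	False	28	False	36	False	43	False
T031	68	male	non-smoker	III	40	P-SCLC	False	35	True	39	False	50	False
T032	69	female	non-smoker	III	45	P-SCLC	False	37	False	42	False	57	False
T033	70	female	non-smoker	III	50	P-SCLC	False	39	False	45	False	64	False
T034	71	female	NA	III	60	P-SCLC	False	41	True	48	False	71	False
T035	72	male	smoker	I	80	C-SCLC	True	1	True	6	True	78	True
T036	73	male	smoker	I	100	C-SCLC	True	50	False	54	False	25	True
T037	74	male	smoker	I	150	C-SCLC	True	52	True	57	False	32	False
T038	75	male	non-smoker	II	200	C-SCLC	False	54	False	60	False	39	False
T039	76	female	non-smoker	II	300	C-SCLC	False	56	False	63	False	46	False
T040	76	female	non-smoker	III	420	C-SCLC	False	58	True	66	False	53	False
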