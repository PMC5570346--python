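protein	position	ref	alt	frequency	provenance	physchem
PGM1	19	T	A	singleton	patient_confirmed	1
PGM1	41	Q	R	singleton	patient_confirmed	1
PGM1	62	D	H	singleton	patient_confirmed	1
PGM1	115	T	A	singleton	patient_confirmed	1
PGM1	121	G	R	singleton	patient_confirmed	1
PGM1	230	G	E	singleton	patient_confirmed	1
PGM1	263	D	G	singleton	patient_confirmed	1
PGM1	263	D	Y	singleton	patient_confirmed	1
PGM1	291	G	R	singleton	patient_confirmed	1
PGM1	330	G	R	singleton	patient_confirmed	1
PGM1	336	P	R	singleton	patient_confirmed	1
PGM1	337	T	M	singleton	patient_confirmed	1
PGM1	377	E	K	singleton	patient_confirmed	1
PGM1	388	E	K	singleton	patient_confirmed	1
PGM1	422	R	W	singleton	patient_confirmed	1
PGM1	503	R	Q	singleton	patient_confirmed	1
PGM1	508	G	R	singleton	patient_confirmed	1
PGM1	515	R	L	singleton	patient_confirmed	1
PGM1	515	R	Q	singleton	patient_confirmed	1
PGM1	516	L	P	singleton	patient_confirmed	1
PGM3	41	R	L	singleton	patient_confirmed	1
PGM3	83	L	S	singleton	patient_confirmed	1
PGM3	239	D	H	singleton	patient_confirmed	1
PGM3	246	N	S	singleton	patient_confirmed	1
PGM3	297	D	E	singleton	patient_confirmed	1
PGM3	379	F	L	singleton	patient_confirmed	1
PGM3	451	Q	R	singleton	patient_confirmed	1
PGM3	502	D	Y	singleton	patient_confirmed	1
PGM1	38	N	Y	singleton	population	1
PGM1	41	Q	E	singleton	population	1
PGM1	41	Q	H	singleton	population	1
PGM1	121	G	W	singleton	population	1
PGM1	139	A	T	singleton	population	1
PGM1	261	H	D	singleton	population	1
PGM1	288	D	G	singleton	population	1
PGM1	330	G	S	lt_1e-4	population	1
PGM1	375	G	V	lt_1e-4	population	1
PGM1	380	G	R	lt_1e-4	population	1
PGM1	422	R	Q	singleton	population	1
PGM1	505	S	R	singleton	population	1
PGM1	506	G	S	singleton	population	1
PGM1	511	G	R	lt_1e-4	population	1
PGM1	515	R	W	lt_1e-4	population	1
PGM2	165	S	P	singleton	population	1
PGM2	166	H	D	singleton	population	1
PGM2	322	D	N	lt_1e-4	population	1
PGM2	322	D	E	singleton	population	1
PGM2	323	P	L	between_1e-4_and_1e-3	population	1
PGM2	324	D	H	singleton	population	1
PGM2	324	D	G	singleton	population	1
PGM2	428	G	E	singleton	population	1
PGM2	558	R	C	lt_1e-4	population	1
PGM2	558	R	H	between_1e-4_and_1e-3	population	1
PGM2	563	E	V	singleton	population	1
PGM2L1	178	R	C	lt_1e-4	population	1
PGM2L1	291	Q	K	singleton	population	1
PGM2L1	332	D	V	singleton	population	1
PGM2L1	334	D	E	lt_1e-4	population	1
PGM2L1	431	F	L	singleton	population	1
PGM2L1	432	A	E	singleton	population	1
PGM2L1	433	F	S	singleton	population	1
PGM2L1	435	E	G	singleton	population	1
PGM2L1	437	I	T	lt_1e-4	population	1
PGM2L1	520	C	Y	singleton	population	1
PGM2L1	571	G	R	lt_1e-4	population	1
PGM3	41	R	H	lt_1e-4	population	1
PGM3	63	A	V	singleton	population	1
PGM3	369	F	I	singleton	population	1
PGM3	372	N	Y	singleton	population	1
PGM3	496	R	W	lt_1e-4	population	1
PGM3	501	E	Q	singleton	population	1
PGM3	501	E	G	singleton	population	1
PGM3	505	R	Q	singleton	population	1
PGM5	295	D	V	lt_1e-4	population	1
PGM5	383	S	R	singleton	population	1
PGM5	386	T	I	singleton	population	1
PGM5	427	R	C	singleton	population	1
PGM5	427	R	H	lt_1e-4	population	1
PGM5	508	R	W	lt_1e-4	population	1
PGM5	508	R	Q	lt_1e-4	population	1
PGM5	513	S	R	between_1e-4_and_1e-3	population	1
PGM5	516	R	W	lt_1e-4	population	1
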