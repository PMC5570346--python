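	PGM1	PGM2	PGM2L1	PGM3	PGM5
adipocyte	8.72	30.715	12.368	41.87	25.516
adrenal gland	17.237	15.643	16.138	24.35	55.882
appendix		18.095	17.858	21.448	10.824
bladder	29.58	12.406	15.676	19.043	19.941
breast	26.429	14.43	11.41	29.748	17.24
colon	23.176	16.16	44.8	18.547	24.256
duodenum	23.136	10.848	13.489	57.2	19.565
esophagus	14.93	6.654	15.772	13.219	1387.533
gall bladder	13.325	10.711	12.28	14.524	45.558
heart	11.9	22.752		27.383	12.675
ileum epithelia	24.019	27.386	13.812	32.38	35.64
kidney	114.324	16.85	16.953	12.181	32.971
liver	155.735	14.895	12.167	25.765	18.474
lung	187.146	18.9	21.227	17.842	19.886
lymph node	21.224	185.927	30.773	22.525	47.873
ovary	14.594	20.872	21.895	14.186	12.534
pancreas	38.306	14.943	36.085	36.3	18.567
placenta	18.764	16.741	30.528	192.145	11.785
prefrontal cortex	17.036	37.234	299.88	19.877	28.148
prostate	23.012	21.702	11.819	9.498	14.911
rectum	27.94	39.509	20.264	13.754	26.755
retina	15.1	11.525	25.508	12.705	19.244
salivary gland	24.61	37.157	20.548	110.162	28.304
skin	21.568	141.097	25.054	11.015	17.069
spleen	13.185	37.76	38.84	15.796	100.29
stomach	26.561	8.91	29.444	18.456	15.458
testis	42.37	24.261	13.382	165.261	24.303
thyroid	18.597	16.48	17.673	110.533	16.987
tonsil	17.747	132.562	27.65	27.012	22.806
uterus	10.344	17.597	16.206	17.613	38.75
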