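	PGM1	PGM2	PGM2L1	PGM3	PGM5
adipocyte	3012.299	148.797	106.196	347.736	865.604
adrenal gland	776.987	358.041	171.863	299.874	308.848
appendix	335.065	415.251	86.134	775.174	401.222
bladder	665.921	493.697	71.676	633.733	3223.604
breast	811.686	359.946	187.857		810.829
colon	472.385	248.145	67.606	459.178	379.524
duodenum	296.567	373.419	202.037	604.084	240.691
esophagus	443.147	786.934	165.66	636.681	311.001
gall bladder	336.295	375.219	156.889	199.906	302.915
heart	300.6	314.734	180.276	367.526	343.659
ileum epithelia	507.591	388.705	64.291	1644.007	322.543
kidney	894.696	318.95	60.529	365.589	565.854
liver	2460.636	540.574	243.277	161.83	232.726
lung	1575.271	275.112	98.756	513.23	542.685
lymph node	384.998	3089.653	124.124	511.039	317.212
ovary	604.13	604.594	60.159	328.641	167.673
pancreas	359.878	312.486	102.296	525.418	793.004
placenta	277.086	393.842	153.298	253.169	334.624
prefrontal cortex	307.877	523.889	7790.305	414.844	494.938
prostate	466.796	489.63	56.331	568.406	3727.881
rectum	248.942	699.32	79.878	210.704	2089.761
retina	390.431	4723.719		401.356	562.008
salivary gland	195.517	386.788	90.914	2393.574	452.284
skin	259.906	604.304	87.183	2089.366	465.099
spleen	398.334	2555.778	58.543	963.129	1892.535
stomach	427.003	318.431	181.246	356.444	1866.633
testis	271.085	461.971	81.793	517.282	591.71
thyroid	321.826	549.225	124.915	349.369	309.196
tonsil	859.288	484.241	40.311	526.732	204.454
uterus	345.729	379.784	88.866	215.114	2446.741
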