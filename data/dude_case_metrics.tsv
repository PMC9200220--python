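name	auc	accuracy	tpr	precision	mcc	pos_num	neg_num
3PBL	0.9479	0.9089	0.9083	0.9977	0.4347	480	14
3KRJ	0.7976	0.8304	0.8434	0.979	0.1108	166	5
830C	0.7593	0.9465	0.979	0.9655	0.2504	572	26
1LRU	0.815	0.7273	0.7353	0.9615	0.206	102	8
3CHP	0.7334	0.849	0.8713	0.9551	0.4302	171	21
2ZDT	0.8524	0.8189	0.8365	0.9355	0.5007	104	23
2ETR	0.7707	0.7826	0.81	0.931	0.3217	100	15
2OJ9	0.9048	0.8072	0.7703	0.9268	0.6177	148	75
2FSZ	0.8414	0.7789	0.782	0.9082	0.5018	367	126
2AYW	0.8323	0.8587	0.9198	0.9037	0.5584	449	117
1ZW5	0.9089	0.9018	1	0.8854	0.7244	85	27
2ICA	0.8126	0.7725	0.8333	0.8846	0.2883	138	29
2NNQ	0.8976	0.8413	0.9787	0.8364	0.5441	47	16
1SJ0	0.8385	0.79	0.9138	0.8216	0.4071	383	136
2HZI	0.7618	0.7669	0.8516	0.8158	0.4476	182	84
2E1W	0.8169	0.7556	0.8495	0.8061	0.4121	93	42
3KL6	0.7082	0.7938	0.9572	0.8056	0.355	537	176
1E66	0.8738	0.8074	0.8631	0.7667	0.6206	453	487
3EL8	0.7293	0.7374	0.9256	0.736	0.3912	524	287
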