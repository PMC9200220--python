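pdb_id	gene_name	ratio_099
3CCW	HMDH	12353
1XL2	HIVPR	4552
2AYW	TRY1	1084
1B9V	NRAM	816.3
1ZW5	FPPS	803.9
3LQ8	MET	697.1
2ZEC	TRYB1	405
2V3F	GLCM	324
1SYN	TYSY	137.6
3G6Z	RENI	98.2
3KL6	FA10	80.4
1LI4	SAHH	79.3
3BKL	ACE	71
3E37	FNTA	68.4737
1SQT	UROK	67.619
1NJS	PUR2	48.9796
1LRU	DEF	46.6341
3F9M	HXK4	43.4
3EQH	MP2K1	40.5
2E1W	ADA	35.0972
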