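# rCRS feature map (NC_012920 annotation): 13 protein genes, 2 rRNAs, 22 tRNAs
# and the control region (split across the origin: 16024-16569 wraps to 1-576).
# Coordinates are 1-based inclusive. strand: H = heavy, L = light (annotated on the
# reverse complement). frame_offset is reserved (0 for all standard mito genes).
gene	start	end	kind	strand	frame_offset
MT-CR	16024	16569	control	H	0
MT-CR	1	576	control	H	0
MT-TF	577	647	tRNA	H	0
MT-RNR1	648	1601	rRNA	H	0
MT-TV	1602	1670	tRNA	H	0
MT-RNR2	1671	3229	rRNA	H	0
MT-TL1	3230	3304	tRNA	H	0
MT-ND1	3307	4262	protein	H	0
MT-TI	4263	4331	tRNA	H	0
MT-TQ	4329	4400	tRNA	L	0
MT-TM	4402	4469	tRNA	H	0
MT-ND2	4470	5511	protein	H	0
MT-TW	5512	5579	tRNA	H	0
MT-TA	5587	5655	tRNA	L	0
MT-TN	5657	5729	tRNA	L	0
MT-TC	5761	5826	tRNA	L	0
MT-TY	5826	5891	tRNA	L	0
MT-CO1	5904	7445	protein	H	0
MT-TS1	7446	7514	tRNA	L	0
MT-TD	7518	7585	tRNA	H	0
MT-CO2	7586	8269	protein	H	0
MT-TK	8295	8364	tRNA	H	0
MT-ATP8	8366	8572	protein	H	0
MT-ATP6	8527	9207	protein	H	0
MT-CO3	9207	9990	protein	H	0
MT-TG	9991	10058	tRNA	H	0
MT-ND3	10059	10404	protein	H	0
MT-TR	10405	10469	tRNA	H	0
MT-ND4L	10470	10766	protein	H	0
MT-ND4	10760	12137	protein	H	0
MT-TH	12138	12206	tRNA	H	0
MT-TS2	12207	12265	tRNA	H	0
MT-TL2	12266	12336	tRNA	H	0
MT-ND5	12337	14148	protein	H	0
MT-ND6	14149	14673	protein	L	0
MT-TE	14674	14742	tRNA	L	0
MT-CYB	14747	15887	protein	H	0
MT-TT	15888	15953	tRNA	H	0
MT-TP	15956	16023	tRNA	L	0
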