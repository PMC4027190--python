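id	rs_id	mirna	targeted_allele	allele_class	delta_score	delta_mfe
Met1Lys	rs121434556	hsa-miR-4498	T	WT	179	-26.73
Met1Lys	rs121434556	hsa-miR-637	T	WT	165	-28.35
Met1Lys	rs121434556	hsa-miR-4446-3p	T	WT	163	-25.07
Met1Lys	rs121434556	hsa-miR-1909-3p	T	WT	154	-26.95
Met1Lys	rs121434556	hsa-miR-4656	A	SNP	147	-26.64
Asn38Ser	rs41427445	hsa-miR-671-3p	G	SNP	199	-26.6
Asn38Ser	rs41427445	hsa-miR-1301-3p	G	SNP	189	-26.71
Asn38Ser	rs41427445	hsa-miR-22-3p	G	SNP	184	-17.96
Asn38Ser	rs41427445	hsa-miR-657	G	SNP	172	-18.12
Thr40=	rs139837207	hsa-miR-4727-5p	T	SNP	210	-24.92
Gln43His	rs142807270	hsa-miR-3127-3p	G	WT	172	-25.72
Gln43His	rs142807270	hsa-miR-1260b	G	WT	169	-22.79
Arg98Leu	rs140352541	hsa-miR-762	G	WT	167	-27.46
Asn127Lys	rs3918252	hsa-miR-3921	G	SNP	168	-15.16
Asn127Lys	rs3918252	hsa-miR-4684-3p	G	SNP	164	-16.55
Arg239His	rs28763886	hsa-miR-449c-5p	G	WT	179	-23.05
Glu274Asp	rs141318648	hsa-miR-1233	G	WT	165	-19.31
Glu274Asp	rs141318648	hsa-miR-611	C	SNP	126	-26.45
Gln279Arg	rs17576	hsa-miR-3934-5p	G	SNP	167	-20.99
Gln279=	rs139262778	hsa-miR-4685-5p	G	WT	131	-27.99
Gln279Arg	rs17576	hsa-miR-1247-5p	G	SNP	128	-25.24
Cys302Ter	rs146499495	hsa-miR-369-5p	A	SNP	169	-15.74
Cys302Ter	rs146499495	hsa-miR-4479	C	WT	168	-22.03
Cys314=	rs139509848	hsa-miR-4726-5p	C	WT	143	-25.91
Gly344=	rs138668828	hsa-miR-4707-5p	G	WT	125	-25.32
Cys347Tyr	rs145450508	hsa-miR-3714	G	WT	133	-25.2
Pro459Ser	rs147087483	hsa-miR-4723-5p	T	SNP	185	-23.76
Ala525=	rs80077409	hsa-miR-671-3p	G	WT	165	-20.22
Asp558Gly	rs150224695	hsa-miR-608	G	SNP	165	-24.19
Pro561Ser	rs141966515	hsa-miR-663a	T	SNP	166	-34.67
Phe571Val	rs35691798	hsa-miR-5192	G	SNP	172	-24.82
Ala608fs	rs34003985	hsa-miR-4787-3p	-	SNP	144	-25.56
Asp608fs	rs34003985	hsa-miR-668	-	SNP	167	-31.53
Arg621Lys	rs6104428	hsa-miR-3194-5p	G	WT	143	-27.06
Arg668Gln	rs17577	hsa-miR-4783-3p	G	WT	171	-25.2
Arg668Gln	rs17577	hsa-miR-4763-5p	C	SNP	142	-26.49
V682M	rs137904662	hsa-miR-28-5p	G	WT	174	-15.99
Ser686Asn	rs151173908	hsa-miR-133a	G	WT	167	-21.37
Ser686Asn	rs151173908	hsa-miR-133b	G	WT	167	-21.37
3'UTR-C3T	rs20544	hsa-miR-4673	T	SNP	165	-19.64
3'UTR-A39C	rs1056628	hsa-miR-4746-5p	C	SNP	185	-20.13
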