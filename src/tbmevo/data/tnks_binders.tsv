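partner	role	arg_residue	tbm_seq	truncated
AMOT	Hippo/YAP signaling	77	RQEPQGQE	0
Arpin	Cell migration	213	REQGDGAE	0
ATG9A	Pexophagy	233	RLPGLGEA	0
Axin1	Wnt signaling	22	RPPVPGEE	0
CASC3	Pre-mRNA splicing	146	RQSGDGQE	0
Dicer1	RNA interference	656	RELPDGTF	0
GMD	GDP-mannose 4,6 dehydratase	12	RGSGDGEM	0
Golgin-45	Golgi structure and protein maturation	18	RGAGDGME	0
IRAP	Vesicle trafficking	96	RQSPDGAC	0
Mcl-1	Apoptosis regulation	78	RPPPIGAE	0
MERIT40	DNA damage repair	28	RSNPEGAE	0
MERIT40	DNA damage repair	48	RSEGEGEA	0
NKD2	Wnt signaling	16	RESPEGDS	0
Notch2	Notch signaling	1726	RREPVGQD	0
NuMA	Mitotic spindle assembly	1743	RTQPDGTS	0
PEX14	Peroxisome homeostasis	310	RMEVQGEE	0
PEX14	Peroxisome homeostasis	350	RRGGDGQI	0
SH3BP2	Osteoclast formation	415	RSPPDGQS	0
SH3BP5	Epithelial lumen formation	269	RGCGVGAE	0
SH3BP5	Epithelial lumen formation	368	RSECSGAS	0
SOX9	Chondrocyte differentiation	257	RPLPEGGR	0
SOX9	Chondrocyte differentiation	271	RDVDIGEL	0
Striatin	Dendritic Ca2+ signaling	302	RSAGDGTD	0
TAB182	Cytoskeletal maintenance	1508	RPQPDGEA	0
TRF1	Telomere maintenance	13	RGCADGRD	0
USP25	Ubiquitin protease	1049	RTPADGR	1
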