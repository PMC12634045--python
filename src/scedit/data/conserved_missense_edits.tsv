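gene	flybase_id	position	previously_annotated	pfam_domain	conservation	original_codon	edited_codon	original_aa	edited_aa
qvr	FBgn0260499	2R:11447607	Yes	QVR	Insects	AGT	GGT	S	G
Shab	FBgn0262593	3L:2925255	Yes	T1-type_BTB	Insects	AGT	GGT	S	G
Shab	FBgn0262593	3L:2941312	Yes	Ion_trans_dom	Mammals	ACA	GCA	T	A
Shab	FBgn0262593	3L:2941364	Yes	Ion_trans_dom	Mammals	TAT	TGT	Y	C
Shab	FBgn0262593	3L:2941396	Yes	Ion_trans_dom	Insects	ACT	GCT	T	A
CG1090	FBgn0037238	3R:4365385	Yes	NaCa_Exmemb	Mammals	AGC	GGC	S	G
Atpalpha	FBgn0002921	3R:20964328	Yes	.	Mammals	GAG	GGG	E	G
Atpalpha	FBgn0002921	3R:20965039	Yes	.	Insects	TAC	TGC	Y	C
slo	FBgn0003429	3R:24675663	Yes	Ion_trans_dom	Mammals	AAT	GAT	N	D
OtopLa	FBgn0259994	X:5631048	Yes	Otopetrin	Insects	ACT	GCT	T	A
para	FBgn0285944	X:16464719	Yes	Ion_trans_dom	Insects	AAC	AGC	N	S
para	FBgn0285944	X:16482682	Yes	Ion_trans_dom	Insects	AAT	GAT	N	D
Sh	FBgn0003380	X:17930658	Yes	.	Mammals	ACG	GCG	T	A
cpx	FBgn0041605	3R:4297517	Yes	Synaphin	Mammals	AAT	GAT	N	D
cpx	FBgn0041605	3R:4297518	Yes	Synaphin	Mammals	AAT	AGT	N	S
lap	FBgn0086372	3R:7192775	Yes	.	Insects	ACA	GCA	T	A
Rbp	FBgn0262483	3R:15399446	Yes	.	Insects	ACC	GCC	T	A
Rim	FBgn0053547	3R:17881419	No	.	Insects	AGA	GGA	R	G
EndoA	FBgn0038659	3R:18907675	Yes	BAR_dom	Mammals	AAG	GAG	K	E
VhaAC45RP	FBgn0051030	3R:30165949	No	.	Insects	GAG	GGG	E	G
cac	FBgn0263111	X:11971853	Yes	Ion_trans_dom	Insects	AGT	GGT	S	G
nAChRalpha6	FBgn0032151	2L:9809349	Yes	Neur_chan_lig-bd	Insects	AAC	AGC	N	S
nAChRalpha6	FBgn0032151	2L:9809350	Yes	Neur_chan_lig-bd	Insects	AAC	GAC	N	D
nAChRalpha5	FBgn0028875	2L:14089204	Yes	Neurotrans-gated_channel_TM	Mammals	ACA	GCA	T	A
Prosap	FBgn0040752	2R:14062651	Yes	.	Insects	CAG	CGG	Q	R
nAChRbeta1	FBgn0000038	3L:4432487	Yes	Neur_chan_lig-bd	Insects	AGA	GGA	R	G
CG1265	FBgn0035517	3L:4255132	No	.	Mammals	GAG	GGG	E	G
bsk	FBgn0000229	2L:10248292	No	Prot_kinase_dom	Mammals	GAC	GGC	D	G
CalpB	FBgn0025866	3L:9892134	Yes	.	Mammals	AAT	AGT	N	S
betaTub56D	FBgn0284243	2R:19447593	No	.	Mammals	GAC	GGC	D	G
CG13506	FBgn0034723	2R:22391510	Yes	.	Insects	CAG	CGG	Q	R
CG32264	FBgn0052264	3L:3717400	No	.	Mammals	AGG	GGG	R	G
Snx21	FBgn0031457	2L:2764358	No	.	.	GAG	GGG	E	G
Sec23	FBgn0262125	3R:5650231	Yes	Sec23/24_trunk_dom	Mammals	CAG	CGG	Q	R
Sec23	FBgn0262125	3R:5650351	Yes	Sec23/24_trunk_dom	Mammals	CAG	CGG	Q	R
CG42613	FBgn0261262	3R:18969789	No	CUB_dom	Insects	GAT	GGT	D	G
muc	FBgn0283658	2L:7429847	No	2-oxoacid_DH_actylTfrase	Mammals	GAG	GGG	E	G
Opa1	FBgn0261276	2R:14234798	No	.	Mammals	AAT	GAT	N	D
bonsai	FBgn0026261	2R:22638356	No	Ribosomal_uS15	Insects	GAC	GGC	D	G
RNaseZ	FBgn0028426	2R:10307375	No	.	Mammals	GAA	GGA	E	G
Hr78	FBgn0015239	3L:21494397	No	Nucl_hrmn_rcpt_lig-bd	Mammals	GAG	GGG	E	G
beag	FBgn0037660	3R:9063537	No	RED_C	Insects	AGC	GGC	S	G
Sxl	FBgn0264270	X:7085816	Yes	.	Insects	AGC	GGC	S	G
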