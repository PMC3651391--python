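# Evidence-classified MSH6 germline missense variants (34 carriers).
# label: LLS = likely Lynch syndrome (pathogenic), ULS = unlikely (non-pathogenic).
# printed_definition: the criterion numbers given with the source table row.
# dataset: training = rows used to fit the logistic coefficients (no functional assay);
#          test = rows held out for the prediction test (with functional assay / normal MMR).
# Enum fields: normal / abnormal / inconclusive / nd / na; msi: H / L / S / nd.
# maf encoding: rows reported as polymorphisms (MAF >= 0.01) carry 0.01; rows reported
# as MAF < 0.01 carry 0.001; unreported carry '.'.
# provenance: source table and row of the publication the dataset was curated from.
# K728T IHC is encoded normal/normal/normal following the narrative ("normal staining
# pattern in IHC" for the four ULS-2 carriers); the typeset table row conflicts with
# its own printed definition there. L396V MSI printed "L/H" is encoded as H.
variant	label	printed_definition	dataset	ihc_mlh1	ihc_msh2	ihc_msh6	msi	assay_mmr_activity	assay_msh2_interaction	assay_localization	assay_atp_hydrolysis	assay_mismatch_recognition	segregation_supportive	family_history_met	proband_tumor_met	control_freq_zero_n100	maf	provenance
G566R	LLS	1	test	nd	nd	nd	H	inconclusive	normal	nd	abnormal	nd	nd	nd	nd	nd	.	Table2:1
R976H	LLS	1,2	test	normal	normal	abnormal	H	nd	normal	nd	nd	abnormal	nd	nd	nd	nd	.	Table2:2
G1139S	LLS	1,2	test	normal	inconclusive	abnormal	H	nd	nd	nd	abnormal	nd	nd	nd	nd	nd	.	Table2:3
S1188N	LLS	1,2	test	normal	normal	abnormal	H	abnormal	nd	nd	nd	nd	nd	nd	nd	nd	.	Table2:4
E1193K	LLS	1,2	test	normal	inconclusive	abnormal	H	abnormal	abnormal	nd	nd	nd	nd	nd	nd	nd	.	Table2:5
L449P	LLS	2,3	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	yes	yes	nd	.	Table3:6
C559Y	LLS	3	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	yes	yes	yes	nd	.	Table3:7
P591S	LLS	2,3	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	yes	yes	yes	.	Table3:8
P623L	LLS	3	training	normal	normal	abnormal	L	nd	nd	nd	nd	nd	nd	no	yes	yes	.	Table3:9
G670R	LLS	2	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	no	no	nd	.	Table3:10
R772W	LLS	2	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	no	no	inconclusive	.	Table3:11
Y969C	LLS	2,3	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	yes	yes	yes	inconclusive	.	Table3:12
G1069E	LLS	2	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	no	no	nd	.	Table3:13
R1076C	LLS	3	training	normal	normal	abnormal	nd	nd	nd	nd	nd	nd	nd	yes	yes	nd	.	Table3:14
A1236P	LLS	2,3	training	normal	normal	abnormal	H	nd	nd	nd	nd	nd	nd	yes	nd	yes	.	Table3:15
R128L	ULS	2	test	abnormal	normal	normal	H	normal	normal	nd	nd	nd	nd	nd	nd	nd	.	Table4:16
S144I	ULS	2,3	test	normal	normal	normal	S	normal	normal	nd	nd	nd	nd	nd	nd	nd	0.001	Table4:17
L396V	ULS	1,2	test	normal	normal	normal	H	normal	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table4:18
K728T	ULS	2,3	test	normal	normal	normal	S	normal	normal	nd	nd	nd	nd	nd	nd	nd	.	Table4:19
K13T	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.001	Table5:20
A25V	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:21
G39E	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:22
G54A	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	.	Table5:23
S65L	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.001	Table5:24
C196F	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:25
R468H	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.001	Table5:26
S503C	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.001	Table5:27
R635G	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	.	Table5:28
I886V	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:29
I1054F	ULS	3	training	normal	normal	normal	S	nd	nd	nd	nd	nd	nd	nd	nd	nd	.	Table5:30
E1163V	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:31
E1196K	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:32
E1234Q	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:33
E1304K	ULS	1	training	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	nd	0.01	Table5:34
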