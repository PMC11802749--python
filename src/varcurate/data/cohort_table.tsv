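gene	rsid	frequency	clnsig	disease	case_study
COG5	rs1449966934	1	Pathogenic	COG5 congenital disorder of glycosylation	AF
CDKN2B-AS1	rs1063192	76	Likely pathogenic	Malignant tumor of breast, three vessel coronary disease	HF
CDKN2B-AS1	rs1333049	70	Risk factor	Three vessel coronary disease	HF
CDKN2B-AS1	rs4977574	70	Risk factor	Three vessel coronary disease	HF
CDKN2B-AS1	rs10757274	71	Risk factor	Three vessel coronary disease	HF
FTO	rs1421085	70	Risk factor	Obesity (BMIQ14) susceptibility	HF
ABO	rs947073006	90	Association	ABO blood group system	HF
ABO	rs977371848	90	Association	ABO blood group system	HF
ABO	rs992108547	90	Association	ABO blood group system	HF
ARNT2	rs3901896	55	Association	Pulmonary disease susceptibility	AF
ARNT2	rs8041826	31	Association	Pulmonary disease susceptibility	AF
CDK6	rs42034	40	Association	Bechet disease	AF
CDK6	rs2282983	65	Association	Bechet disease	AF
CELSR2	rs12740374	32	Association	LDL cholesterol	HF
CREB5	rs4722804	30	Association	Vascular endothelial growth factor inhibitor response	AF
SLC35F1	rs11153718	34	Association	Vascular endothelial growth factor inhibitor response	AF
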