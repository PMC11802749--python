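gene	rsids	disease
AGBL4	rs11590635	AF
AKAP6	rs2145587;rs11156751	AF
ANXA4	rs3771537	AF
ARHGAP10	rs10213171	AF
ARHGAP26	rs6580277	AF
ASAH1	rs7508	AF
ATXN1	rs73366713	AF
BEST3	rs35349325	AF
C10orf11	rs11001667;rs10458660	AF
C10orf76	rs1044258	AF
C9orf3	rs4385527;rs10821415	AF
C9orf3(FBP1)	rs10821415	AF
C9orf3(FBP2)	rs10821415	AF
CAMK2D	rs55754224;rs6829664	AF
CAND2	rs6810325;rs4642101;rs7650482	AF
CASQ2	rs4484922;rs4073778	AF
CASZ1	rs880315;rs284277	AF
CAV1	rs11773845;rs3807989	AF
CDK6	rs11773884;rs56201652	AF
CDKN1A	rs3176326	AF
CEP68	rs2540949	AF
CFL2	rs73241997	AF
COG5	rs62483627	AF
CREB5	rs6462078;rs6462079	AF
CUL4A	rs35569628	AF
CUX2	rs6490029	AF
CYTH1	rs12604076	AF
DGKB	rs55734480	AF
DNAH10	rs12298484	AF
DPF3	rs74884082	AF
EPHA3	rs7632427;rs6771054	AF
ERBB4	rs35544454	AF
FAM13B	rs2967791	AF
FBN2	rs2012809	AF
FBRSL1	rs6560886	AF
FBXO32	rs62521286	AF
FRMD4B	rs17005647	AF
GMCL1	rs3771537	AF
GNB4	rs4855075;rs7612445	AF
GOPC	rs210632	AF
GOSR2	rs76774446	AF
GTF2I	rs74910854;rs35005436	AF
GYPC	rs28387148	AF
HAND2	rs10520260	AF
HCN4	rs7164883	AF
HIP1R	rs10773657	AF
IGF1R	rs12908437;rs4965430	AF
KCND3	rs12044963;rs1545300	AF
KCNH2	rs7789146	AF
KCNJ5	rs76097649;rs75190942	AF
KCNN2	rs716845;rs337711;rs337705	AF
KDM1B	rs34969716	AF
KIF3C	rs6546620;rs7578393	AF
KLHL3	rs2967791	AF
LHX3	rs2274115	AF
LINC00964	rs35006907	AF
LRIG1	rs2306272;rs34080181	AF
MAPT	rs242557	AF
MBD5	rs12992412	AF
MEX3C	rs8088085	AF
MIR30B	rs7460121	AF
MTSS1	rs35006907;rs35006907	AF
MYH7	rs28631169;rs422068	AF
MYO18B	rs133902	AF
MYOCD	rs72811294	AF
MYOZ1	rs10824026	AF
NACA	rs7978685;rs2860482	AF
NAV2	rs1822273;rs10741807	AF
NKX2-5	rs6882776	AF
NME5	rs2040862	AF
NR3C1	rs6580277	AF
NUCKS1	rs4951261;rs4951258	AF
OPN1SW	rs55985730	AF
PAK2	rs9872035	AF
PCM1	rs7508	AF
PHLDB2	rs17490701;rs10804493	AF
PKP2	rs12809354	AF
PLN	rs4946333;rs89107	AF
POLR2A	rs9899183	AF
PPFIA4	rs10753933;rs17461925	AF
PPP2R3A	rs1278493	AF
PSMB7	rs10760361	AF
PTK2	rs6993266;rs6994744	AF
RBM20	rs10749053	AF
REEP3	rs7919685;rs12245149	AF
RPS2	rs2286466	AF
SCMH1	rs2885697	AF
SCN10A	rs6790396;rs6800541	AF
SH3PXD2A	rs2047036	AF
SIRT1	rs7096385	AF
SLC27A6	rs2012809	AF
SLC35F1	rs17079881;rs4946333;rs89107;rs3951016	AF
SLC9B1	rs3960788;rs10006327	AF
SLIT3	rs12188351	AF
SMAD7	rs9953366	AF
SNRNP27	rs10165883;rs6747542	AF
SNX6	rs73241997	AF
SPATS2L	rs295114;rs3820888	AF
SSPN	rs113819537;rs17380837	AF
SUN1	rs11768850	AF
SYNE2	rs2738413;rs1152591	AF
SYNPO2L	rs60212594;rs10824026	AF
TBX5	rs883079;rs10507248	AF
TEX41	rs67969609	AF
THRB	rs73032363;rs73041705	AF
TNFSF12	rs9899183	AF
TTN	rs35504893;rs2288327	AF
TTN-AS1	rs2288327	AF
TUBA8	rs465276;rs464901	AF
USP3	rs62011291	AF
UST	rs117984853	AF
WDR1	rs3822259	AF
WNT8A	rs2967791;rs2040862	AF
XPO1	rs6742276	AF
XPO7	rs7846485;rs7834729	AF
XXYLT1	rs60902112	AF
ZFHX3	rs2359171;rs2106261	AF
ZNF462	rs4743034	AF
ZPBP2	rs11658278	AF
AGAP5	rs4746140	HF
ATXN2	rs4766578	HF
BAG3	rs17617337;rs2234962	HF
CDKN1A	rs4135240	HF
CDKN2B-AS1	rs1556516	HF
CELSR2	rs660240	HF
KLHL3	rs11745324	HF
LINC00964	rs35006907	HF
LPA	rs55730499;rs140570886	HF
MAP7D1	rs272825;rs272832	HF
MTSS1	rs35006907;rs34866937;rs35006907	HF
NMB	rs2175567;rs17598603	HF
SCN5A	rs1805126	HF
SH2B3	rs7310615	HF
SURF1	rs600038	HF
SYNPOL2L	rs4746140	HF
TTN	rs2042995;rs2255167	HF
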