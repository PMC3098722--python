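target	conformers	binders	decoys	total	ratio	chemotypes
ACE_HUMAN	7	46	996	1042	0.046	18
ACES_TORCA	21	99	3859	3958	0.025	18
ADA_BOVIN	13	23	927	950	0.024	8
ALDR_HUMAN	15	46	1796	1842	0.025	14
AMPC_COLI	16	21	786	807	0.026	6
ANDR_HUMAN	29	68	2848	2916	0.023	10
CDK2_HUMAN	30	47	2070	2117	0.022	32
COMT_RAT	3	11	468	479	0.023	2
DHFR_HUMAN	6	190	8350	8540	0.023	14
EGFR_HUMAN	6	365	15560	15925	0.023	40
ESR1_AG_HUMAN	4	63	2568	2631	0.024	10
ESR1_ANT_HUMAN	13	18	1058	1076	0.017	8
F10A_HUMAN	20	64	2092	2156	0.030	19
FGFR1_HUMAN	4	71	3462	3533	0.020	12
GCR_HUMAN	4	32	2585	2617	0.012	9
HMDH_HUMAN	9	25	1423	1448	0.017	4
HS9A_HUMAN	20	23	975	998	0.023	4
INHA_MYCTU	14	57	2707	2764	0.021	23
KITH_HHV11	19	22	891	913	0.025	7
MCR_HUMAN	11	13	636	649	0.020	2
MK14_MOUSE	19	137	6779	6916	0.020	20
NRAM_INBBE	11	49	1713	1762	0.028	7
PARP1_CHICK	6	31	1350	1381	0.023	7
PDE5A_HUMAN	11	26	1698	1724	0.015	22
PGH1_SHEEP	2	23	910	933	0.025	11
PGH2_MOUSE	2	212	7632	7844	0.027	44
PNPH_BOVIN	19	25	1036	1061	0.024	4
POL_HV1RT	18	34	1494	1528	0.022	17
PRGR_HUMAN	6	22	920	942	0.024	4
PUR3_COLI	3	8	155	163	0.051	5
PYGM_RABIT	20	52	2135	2187	0.024	10
RXRA_HUMAN	15	18	575	593	0.031	3
SRC_HUMAN	14	98	5679	5777	0.017	21
THRB_HUMAN	20	23	1148	1171	0.020	14
TRY1_BOVIN	19	9	718	727	0.012	7
VGFR2_HUMAN	8	48	2712	2760	0.017	31
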