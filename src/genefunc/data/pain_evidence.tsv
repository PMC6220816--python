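# Positive genetic-association reports for persisting pain, one row per
# (gene, clinical setting, key reference) as printed in the source table.
# Settings use the 8-label controlled vocabulary; duplicate (gene, setting)
# rows are collapsed by the parser (first reference kept).
gene	ncbi	setting	reference
ACAN	176	musculoskeletal	Kirk_bib0080
ACE	1636	musculoskeletal	Rommel_bib0134
ADRA1A	148	neuropathic	Herlyn_bib0062
ADRA1D	146	visceral	Sugaya_bib0152
ADRA2A	150	idiopathic	Kim_bib0077
ADRA2C	152	idiopathic	Kim_bib0077
ADRB2	154	widespread	Hocking_bib0064
ADRB2	154	musculoskeletal	Diatchenko_bib0038
ADRB2	154	neuropathic	Herlyn_bib0062
ADRB3	155	visceral	Sugaya_bib0152
ANP32A	8125	musculoskeletal	Valdes_bib0167
APOE	348	widespread	Reeser_bib0128
AR	367	visceral	Shaik_bib0144
ASPN	54829	musculoskeletal	Nakamura_bib0115
CACNA2D3	55799	back	Neely_bib0116
CACNG2	10369	neuropathic	Nissenbaum_bib0119
CALCA	796	neuropathic	Herlyn_bib0062
CAMK4	814	miscellaneous	Smith_bib0147
CASP9	842	back	Guo_bib0057
CCT5	22948	widespread	Peters_bib0126
CFTR	1080	inflammatory	Midha_bib0107
CRHBP	1393	widespread	Holliday_bib0065
CILP	8483	back	Seki_bib0143
CNR1	1268	visceral	Park_bib0124
COL1A1	1277	back	Tilkeridis_bib0159
COL6A4P1	344875	musculoskeletal	Miyamoto_bib0108
COL9A2	1298	back	AlaKokko_bib0002
COL9A3	1299	back	Kales_bib0072
COMT	1312	musculoskeletal	vanMeurs_bib0106
COMT	1312	widespread	Cohen_bib0031
COMT	1312	back	Dai_bib0033
COMT	1312	visceral	Karling_bib0074
COMT	1312	idiopathic	Tahara_bib0153
CRH	1392	widespread	Holliday_bib0065
CRHBP	1393	musculoskeletal	Linnstaedt_bib0092
CRHR1	1394	widespread	Holliday_bib0065
CYP2D6	1565	visceral	Wu_bib0178
DIO2	1734	musculoskeletal	Meulenbelt_bib0105
DRD4	1815	musculoskeletal	AneirosGuerrero_bib0004
DRD4	1815	widespread	Buskila_bib0019
LPAR1	1902	musculoskeletal	Mototani_bib0113
ESR1	2099	idiopathic	RibeiroDasilva_bib0132
ESR1	2099	visceral	Govindan_bib0055
ESR1	2099	musculoskeletal	Kang_bib0073
FAM173B	134145	widespread	Peters_bib0126
FKBP5	2289	musculoskeletal	Bortsov_bib0015
GBP1	2633	widespread	Smith_bib0148
GC	2638	visceral	Faserl_bib0046
GCH1	2643	back	Doehring_bib0041
GCH1	2643	widespread	Kim_bib0078
GDF5	8200	musculoskeletal	Valdes_bib0171
GNB3	2784	visceral	Oshima_bib0122
GRK5	2869	miscellaneous	Smith_bib0147
GSTM1	2944	visceral	Wu_bib0178
GSTM1	2944	musculoskeletal	AneirosGuerrero_bib0004
GSTP1	2950	visceral	Woo_bib0177
GSTT1	2952	visceral	Woo_bib0177
HFE	3077	musculoskeletal	Alizadeh_bib0003
HLA-A	3105	neuropathic	Sato_bib0138
HLA-B	3106	neuropathic	deRooij_bib0135
HLA-B	3106	inflammatory	Gullo_bib0056
HLA-C	3107	neuropathic	Ozawa_bib0123
HLA-DQA1	3117	neuropathic	deRooij_bib0135
HLA-DQB1	3119	neuropathic	deRooij_bib0135
HLA-DRB1	3123	neuropathic	Sato_bib0138
HTR2A	3356	visceral	Pata_bib0125
HTR3E	285242	visceral	Kilpatrick_bib0076
IFNG	3458	inflammatory	NoponenHietala_bib0120
IFNG	3458	inflammatory	Oen_bib0121
IFRD1	3475	miscellaneous	Smith_bib0147
IL-10	3586	back	Shoskes_bib0146
IL-10	3586	inflammatory	NoponenHietala_bib0120
IL-10	3586	musculoskeletal	Oen_bib0121
IL-16	3603	visceral	Gan_bib0051
IL-1A	3552	back	Solovieva_bib0149
IL-1B	3553	back	Zhang_bib0179
IL-1B	3553	miscellaneous	Jeremias_bib0068
IL-1R2	7850	neuropathic	Stephens_bib0151
IL-1RN	3557	back	Kim_bib0079
IL-1RN	3557	musculoskeletal	Attur_bib0009
IL-1RN	3557	idiopathic	Witkin_bib0176
IL-2	3558	inflammatory	NoponenHietala_bib0120
IL-4	3565	visceral	Sugaya_bib0152
IL-4	3565	inflammatory	NoponenHietala_bib0120
IL-4R	3566	visceral	Sugaya_bib0152
IL-4R	3566	inflammatory	NoponenHietala_bib0120
IL-6	3569	back	Herlyn_bib0062
IL-6	3569	idiopathic	Shoskes_bib0146
IL-6	3569	inflammatory	NoponenHietala_bib0120
IL-6	3569	neuropathic	Oen_bib0121
KCNJ6	3763	back	Bruehl_bib0018
KCNS1	3787	neuropathic	Costigan_bib0032
MAOA	4128	musculoskeletal	Gursoy_bib0058
MBL2	4153	idiopathic	Babula_bib0010
MC1R	4157	idiopathic	Foster_bib0048
MC2R	4158	widespread	Holliday_bib0065
MIF	4282	visceral	Arisawa_bib0006
SOD2	6648	visceral	Arisan_bib0005
MTHFD1	4522	musculoskeletal	AneirosGuerrero_bib0004
MTRR	4552	musculoskeletal	AneirosGuerrero_bib0004
MYT1L	23040	widespread	Docampo_bib0040
NCR3	259197	neuropathic	Sato_bib0138
NPY	4852	back	Herlyn_bib0062
NR3C1	2908	widespread	Holliday_bib0065
NRXN3	9369	widespread	Docampo_bib0040
NTRK1	4914	miscellaneous	Shatzky_bib0145
OPRM1	4988	miscellaneous	Cheng_bib0026
P2RX7	5027	musculoskeletal	Sorge_bib0150
P2RX7	5027	neuropathic	Sorge_bib0150
PCSK6	5046	musculoskeletal	Malfait_bib0104
PGK1	5230	visceral	Riley_bib0133
PGR	5241	visceral	DeCarvalho_bib0034
POMC	5443	widespread	Holliday_bib0065
PRSS1	5644	inflammatory	Midha_bib0107
PTGS1	5742	visceral	Arisawa_bib0007
SCN5A	6331	visceral	Saito_bib0137
SCN5A	6331	idiopathic	Reimann_bib0129
SCN9A	6335	back	Reimann_bib0129
SCN9A	6335	inflammatory	Reimann_bib0129
SCN9A	6335	miscellaneous	Reimann_bib0129
SCN9A	6335	musculoskeletal	Valdes_bib0169
SCN10A	6336	neuropathic	Faber_bib0045
SCN11A	11280	widespread	Leipold_bib0087
SERPINA1	5265	widespread	Blanco_bib0014
SERPINA6	866	widespread	Holliday_bib0065
SHMT1	6470	idiopathic	AneirosGuerrero_bib0004
SLC6A4	6532	idiopathic	Herken_bib0061
SMAD3	4088	musculoskeletal	Valdes_bib0168
SOD2	6648	idiopathic	Arisan_bib0005
SPINK1	6690	inflammatory	Midha_bib0107
TAAR1	134864	widespread	Smith_bib0148
TAC1	6863	back	Herlyn_bib0062
TACR1	6869	visceral	Renner_bib0130
TGFB1	7040	back	Herlyn_bib0062
TGFB1	7040	inflammatory	Shoskes_bib0146
TGFB1	7040	musculoskeletal	Oen_bib0121
TNF	7124	back	Herlyn_bib0062
TNF	7124	idiopathic	Shoskes_bib0146
TNF	7124	inflammatory	NoponenHietala_bib0120
TNF	7124	musculoskeletal	Oen_bib0121
TP53	7157	visceral	RibeiroJunior_bib0131
TPH2	121278	widespread	Nicholl_bib0118
TPH2	121278	musculoskeletal	Nicholl_bib0118
TRPA1	8989	neuropathic	Binder_bib0012
TRPM8	79054	neuropathic	Binder_bib0012
TRPV1	7442	musculoskeletal	Valdes_bib0170
TRPV1	7442	neuropathic	Binder_bib0012
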