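gene	target_name	degree	betweenness
IL6	Interleukin 6	28	0.034933
TNF	Tumor Necrosis Factor	27	0.029773
AKT1	AKT Serine/Threonine Kinase 1	26	0.02412
ESR1	Estrogen Receptor 1	26	0.044226
TP53	Tumor Protein P53	26	0.022326
VEGFA	Vascular Endothelial Growth Factor A	26	0.017908
EGFR	Epidermal Growth Factor Receptor	25	0.015777
MAPK3	Mitogen-Activated Protein Kinase 3	25	0.014045
PTGS2	Prostaglandin-Endoperoxide Synthase 2	25	0.03103
EGF	Epidermal Growth Factor	24	0.006448
HSP90AA1	Heat Shock Protein 90 Alpha Family Class A Member 1	24	0.011566
PPARA	Peroxisome Proliferator Activated Receptor Alpha	24	0.02819
CASP3	Caspase 3	23	0.00302
FOS	Fos Proto-Oncogene, AP-1 Transcription Factor Subunit	23	0.010306
MYC	MYC Proto-Oncogene, BHLH Transcription Factor	23	0.00302
CCND1	Cyclin D1	22	0.009491
MAPK1	Mitogen-Activated Protein Kinase 1	22	0.004374
MAPK8	Mitogen-Activated Protein Kinase 8	22	0.0021
STAT1	Signal Transducer And Activator Of Transcription 1	21	0.001201
APP	Amyloid Beta Precursor Protein	20	0.007925
CASP8	Caspase 8	20	6.54E-04
IL4	Interleukin 4	19	0.00576
PRKCA	Protein Kinase C Alpha	17	1.04E-04
IGFBP3	Insulin Like Growth Factor Binding Protein 3	16	0.002014
CYP3A4	Cytochrome P450 Family 3 Subfamily A Member 4	13	0.019348
F2	Coagulation Factor II, Thrombin	13	0.007026
CYP1A1	Cytochrome P450 Family 1 Subfamily A Member 1	10	0.006373
APOB	Apolipoprotein B	8	5.92E-04
ADRB2	Adrenoceptor Beta 2	7	4.47E-04
NCOA1	Nuclear Receptor Coactivator 1	7	0.00119
AKR1C3	Aldo-Keto Reductase Family 1 Member C3	4	2.30E-04
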