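n	group	name	abbreviation	n_samples
1	Healthy control	Healthy Control	HC	170
2	Chronic lung diseases	Tuberculosis	TB	5
3	Chronic lung diseases	Acute interstitial pneumonia	AIP	1
4	Chronic lung diseases	Cryptogenic organizing pneumonia	COP	3
5	Chronic lung diseases	Chronic obstructive pulmonary disease	COPD	220
6	Chronic lung diseases	Desquamative interstitial pneumonia	DIP	4
7	Chronic lung diseases	Fibrosis unknown	FU	10
8	Chronic lung diseases	Hypersensitive pneumonitis	HP	30
9	Chronic lung diseases	Interstitial lung disease other	ILD_OTHER	9
10	Chronic lung diseases	Interstitial lung disease unknown	ILD_UNK	14
11	Chronic lung diseases	Nonspecific interstitial pneumonia	NSIP	14
12	Chronic lung diseases	Respiratory bronchiolitis-interstitial lung disease	RB-ILD	12
13	Chronic lung diseases	Pulmonary sarcoidosis	SARC	6
14	Chronic lung diseases	Idiopathic pulmonary fibrosis	UIP_IPF	157
15	Lung cancers	Lung adenocarcinoma	ADC	85
16	Lung cancers	Lung cancer basaloid	BAS	39
17	Lung cancers	Lung cancer carcinoid	CARCI	24
18	Lung cancers	Large cell carcinoma	LCC	3
19	Lung cancers	Lung cancer large cell neuroendocrine	LCNE	56
20	Lung cancers	Lung cancer other	LCO	4
21	Lung cancers	Small cell lung carcinoma	SCC	21
22	Lung cancers	Squamous cell carcinoma	SQC	61
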