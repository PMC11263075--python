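drug,receptor,ki_nM,activity,f_u,c_t_ng_per_ml,mw_g_per_mol,source
aripiprazole,D2,0.8,partial_agonist,0.01,350,448.4,synthetic
aripiprazole,D3,1.0,partial_agonist,0.01,350,448.4,synthetic
aripiprazole,5-HT1A,5.6,partial_agonist,0.01,350,448.4,synthetic
aripiprazole,5-HT2A,8.7,antagonist,0.01,350,448.4,synthetic
aripiprazole,5-HT2C,76,partial_agonist,0.01,350,448.4,synthetic
aripiprazole,5-HT7,10,antagonist,0.01,350,448.4,synthetic
aripiprazole,alpha1,26,antagonist,0.01,350,448.4,synthetic
aripiprazole,H1,28,antagonist,0.01,350,448.4,synthetic
asenapine,D2,1.3,antagonist,0.05,5,285.8,synthetic
asenapine,D3,0.4,antagonist,0.05,5,285.8,synthetic
asenapine,5-HT1A,2.5,partial_agonist,0.05,5,285.8,synthetic
asenapine,5-HT2A,0.06,antagonist,0.05,5,285.8,synthetic
asenapine,5-HT2C,0.03,antagonist,0.05,5,285.8,synthetic
asenapine,5-HT7,0.1,antagonist,0.05,5,285.8,synthetic
asenapine,alpha1,1.2,antagonist,0.05,5,285.8,synthetic
asenapine,alpha2,1.2,antagonist,0.05,5,285.8,synthetic
asenapine,H1,1.0,antagonist,0.05,5,285.8,synthetic
brexpiprazole,D2,0.3,partial_agonist,0.01,40,433.6,synthetic
brexpiprazole,D3,1.1,partial_agonist,0.01,40,433.6,synthetic
brexpiprazole,5-HT1A,0.12,partial_agonist,0.01,40,433.6,synthetic
brexpiprazole,5-HT2A,0.47,antagonist,0.01,40,433.6,synthetic
brexpiprazole,5-HT7,3.7,antagonist,0.01,40,433.6,synthetic
brexpiprazole,alpha1,3.8,antagonist,0.01,40,433.6,synthetic
brexpiprazole,H1,19,antagonist,0.01,40,433.6,synthetic
cariprazine,D2,0.5,partial_agonist,0.04,30,427.4,synthetic
cariprazine,D3,0.09,partial_agonist,0.04,30,427.4,synthetic
cariprazine,5-HT1A,2.6,partial_agonist,0.04,30,427.4,synthetic
cariprazine,5-HT2A,19,antagonist,0.04,30,427.4,synthetic
cariprazine,H1,23,antagonist,0.04,30,427.4,synthetic
clozapine,D2,160,antagonist,0.03,600,326.8,synthetic
clozapine,D3,270,antagonist,0.03,600,326.8,synthetic
clozapine,5-HT1A,120,partial_agonist,0.03,600,326.8,synthetic
clozapine,5-HT2A,5.4,antagonist,0.03,600,326.8,synthetic
clozapine,5-HT2C,9.4,antagonist,0.03,600,326.8,synthetic
clozapine,5-HT7,18,antagonist,0.03,600,326.8,synthetic
clozapine,alpha1,1.6,antagonist,0.03,600,326.8,synthetic
clozapine,alpha2,37,antagonist,0.03,600,326.8,synthetic
clozapine,muscarinic,6.2,antagonist,0.03,600,326.8,synthetic
clozapine,H1,1.1,antagonist,0.03,600,326.8,synthetic
iloperidone,D2,6.3,antagonist,0.03,10,426.5,synthetic
iloperidone,D3,7.1,antagonist,0.03,10,426.5,synthetic
iloperidone,5-HT2A,5.6,antagonist,0.03,10,426.5,synthetic
iloperidone,alpha1,0.3,antagonist,0.03,10,426.5,synthetic
iloperidone,alpha2,3.6,antagonist,0.03,10,426.5,synthetic
iloperidone,H1,12,antagonist,0.03,10,426.5,synthetic
lurasidone,D2,1.0,antagonist,0.01,40,492.7,synthetic
lurasidone,D3,16,antagonist,0.01,40,492.7,synthetic
lurasidone,5-HT1A,6.4,partial_agonist,0.01,40,492.7,synthetic
lurasidone,5-HT2A,2.0,antagonist,0.01,40,492.7,synthetic
lurasidone,5-HT7,0.5,antagonist,0.01,40,492.7,synthetic
lurasidone,alpha2,41,antagonist,0.01,40,492.7,synthetic
olanzapine,D2,21,antagonist,0.07,80,312.4,synthetic
olanzapine,D3,44,antagonist,0.07,80,312.4,synthetic
olanzapine,5-HT2A,3.7,antagonist,0.07,80,312.4,synthetic
olanzapine,5-HT2C,10,antagonist,0.07,80,312.4,synthetic
olanzapine,5-HT7,250,unspecified,0.07,80,312.4,synthetic
olanzapine,alpha1,110,antagonist,0.07,80,312.4,synthetic
olanzapine,muscarinic,24,antagonist,0.07,80,312.4,synthetic
olanzapine,H1,2.2,antagonist,0.07,80,312.4,synthetic
paliperidone,D2,2.8,antagonist,0.26,60,426.5,synthetic
paliperidone,D3,6.7,antagonist,0.26,60,426.5,synthetic
paliperidone,5-HT1A,480,unspecified,0.26,60,426.5,synthetic
paliperidone,5-HT2A,1.2,antagonist,0.26,60,426.5,synthetic
paliperidone,5-HT7,2.7,antagonist,0.26,60,426.5,synthetic
paliperidone,alpha1,2.5,antagonist,0.26,60,426.5,synthetic
paliperidone,alpha2,4.7,antagonist,0.26,60,426.5,synthetic
paliperidone,H1,19,antagonist,0.26,60,426.5,synthetic
quetiapine,D2,380,antagonist,0.17,500,383.5,synthetic
quetiapine,D3,340,antagonist,0.17,500,383.5,synthetic
quetiapine,5-HT1A,320,partial_agonist,0.17,500,383.5,synthetic
quetiapine,5-HT2A,100,antagonist,0.17,500,383.5,synthetic
quetiapine,5-HT7,310,unspecified,0.17,500,383.5,synthetic
quetiapine,alpha1,22,antagonist,0.17,500,383.5,synthetic
quetiapine,alpha2,890,antagonist,0.17,500,383.5,synthetic
quetiapine,muscarinic,110,antagonist,0.17,500,383.5,synthetic
quetiapine,H1,7.5,antagonist,0.17,500,383.5,synthetic
risperidone,D2,3.2,antagonist,0.10,60,410.5,synthetic
risperidone,D3,7.3,antagonist,0.10,60,410.5,synthetic
risperidone,5-HT1A,210,unspecified,0.10,60,410.5,synthetic
risperidone,5-HT2A,0.2,antagonist,0.10,60,410.5,synthetic
risperidone,5-HT2C,32,antagonist,0.10,60,410.5,synthetic
risperidone,5-HT7,1.4,antagonist,0.10,60,410.5,synthetic
risperidone,alpha1,1.4,antagonist,0.10,60,410.5,synthetic
risperidone,alpha2,5.1,antagonist,0.10,60,410.5,synthetic
risperidone,H1,20,antagonist,0.10,60,410.5,synthetic
ziprasidone,D2,4.8,antagonist,0.001,200,412.9,synthetic
ziprasidone,D3,7.2,antagonist,0.001,200,412.9,synthetic
ziprasidone,5-HT1A,3.4,partial_agonist,0.001,200,412.9,synthetic
ziprasidone,5-HT2A,0.4,antagonist,0.001,200,412.9,synthetic
ziprasidone,5-HT2C,1.3,antagonist,0.001,200,412.9,synthetic
ziprasidone,5-HT7,6.0,antagonist,0.001,200,412.9,synthetic
ziprasidone,alpha1,10,antagonist,0.001,200,412.9,synthetic
ziprasidone,H1,47,antagonist,0.001,200,412.9,synthetic
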